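"""Synthetic flowering-record communities, Yule trees and Brownian traits.

The record generator emulates a weekly flowering census (1 March – 31 July)
of a temperate community of insect-pollinated trees, perennial herbs and
annuals.  Each species draws a peak onset date; each individual draws a true
onset around that peak (the within-species onset SD is the synchrony dial)
and a true duration from a gamma distribution parameterized by its mean and
variance (the MFL/VFL dials).  Only what a weekly census would see is
recorded: the first and last census dates covered by the true interval;
individuals whose interval falls entirely between censuses are censored out.

Default parameters encode the observed community structure: 13 tree,
15 perennial and 20 annual species, individual counts between 5 and 69 per
species, trees with small within-species onset dispersion and duration
variance, annuals with large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from ._util import substream
from .records_io import CensusCalendar, Dataset

logger = logging.getLogger(__name__)


@dataclass
class LifeFormParams:
    """Generator dials for one life form (days / days² units)."""

    n_species: int
    n_individuals_range: tuple
    peak_onset_mean: float        # day of year of the mean species peak
    peak_onset_sd_between: float  # SD of species peaks around that mean
    onset_sd_within: float        # within-species onset SD (synchrony)
    mfl_mean: float               # mean individual flowering length
    mfl_sd_between: float         # SD of species mean lengths
    vfl_within: float             # within-species duration variance

    def __post_init__(self):
        if self.n_species < 1 or self.n_individuals_range[0] < 1:
            raise ValueError("counts must be >= 1")
        if min(self.peak_onset_sd_between, self.onset_sd_within,
               self.mfl_sd_between, self.vfl_within) < 0:
            raise ValueError("dispersions must be >= 0")
        if self.mfl_mean < 1:
            raise ValueError("mfl_mean must be >= 1 day")


#: Study-condition defaults: community composition and census protocol of a
#: warm-temperate forest community observed weekly from March to July.
DEFAULT_PARAMS = {
    "tree": LifeFormParams(13, (5, 30), 130.0, 22.0, 3.0, 14.0, 4.0, 9.0),
    "perennial": LifeFormParams(15, (5, 40), 110.0, 25.0, 8.0, 18.0, 5.0, 49.0),
    "annual": LifeFormParams(20, (5, 69), 95.0, 18.0, 12.0, 16.0, 5.0, 100.0),
}


def weekly_calendar(year: int, start: str = "03-01",
                    end: str = "07-31") -> CensusCalendar:
    """Weekly census dates from 1 March to 31 July of one year."""
    dates = pd.date_range(f"{year}-{start}", f"{year}-{end}", freq="7D")
    return CensusCalendar(year, tuple(dates))


@dataclass
class SimManifest:
    seed: int
    species_params: pd.DataFrame
    n_records: int
    n_censored: int
    config: dict = field(default_factory=dict)


def _gamma_mean_var(rng, mean, var, size):
    """Gamma draws parameterized by (mean, variance), truncated at 1 day."""
    if var <= 0:
        return np.full(size, mean)
    shape = mean ** 2 / var
    scale = var / mean
    return np.maximum(rng.gamma(shape, scale, size=size), 1.0)


def _assign_genera(species_order, life_form, max_genus_size=3):
    """Round-robin genus labels over species ordered by peak onset."""
    n = len(species_order)
    n_genera = int(np.ceil(n / max_genus_size))
    return {sp: f"{life_form[:4].capitalize()}genus{(i % n_genera) + 1:02d}"
            for i, sp in enumerate(species_order)}


def simulate_records(cfg: dict = None, calendars=None, seed: int = 0,
                     years=(2016, 2017)) -> tuple:
    """Generate a flowering-record Dataset plus its manifest.

    ``cfg`` maps life form -> LifeFormParams (defaults: DEFAULT_PARAMS).
    ``calendars`` may be one CensusCalendar or a per-year dict; by default
    weekly calendars are built for ``years``.  Species parameters are drawn
    once; individuals are drawn independently per year.  Deterministic for
    a given (cfg, seed).
    """
    cfg = dict(cfg or DEFAULT_PARAMS)
    if calendars is None:
        calendars = {y: weekly_calendar(y) for y in years}
    elif isinstance(calendars, CensusCalendar):
        calendars = {calendars.year: calendars}
    rows, meta_rows, param_rows = [], [], []
    n_censored = 0
    for life_form in sorted(cfg):
        p = cfg[life_form]
        rng = substream(seed, "species_params", life_form)
        peaks = rng.normal(p.peak_onset_mean, p.peak_onset_sd_between,
                           p.n_species)
        mfls = np.maximum(
            rng.normal(p.mfl_mean, p.mfl_sd_between, p.n_species), 2.0)
        counts = rng.integers(p.n_individuals_range[0],
                              p.n_individuals_range[1] + 1, p.n_species)
        names = [f"{life_form.capitalize()}_sp{i + 1:02d}"
                 for i in range(p.n_species)]
        order = [names[i] for i in np.argsort(peaks, kind="stable")]
        genus_of = _assign_genera(order, life_form)
        for i, sp in enumerate(names):
            param_rows.append({
                "species": sp, "life_form": life_form,
                "genus": genus_of[sp], "peak_onset": peaks[i],
                "mfl_true": mfls[i], "n_target": int(counts[i])})
            meta_rows.append({"species": sp, "genus": genus_of[sp],
                              "family": f"{genus_of[sp]}aceae",
                              "life_form": life_form})
            for year, cal in calendars.items():
                r = substream(seed, "individuals", sp, year)
                onsets = r.normal(peaks[i], p.onset_sd_within, counts[i])
                lengths = _gamma_mean_var(r, mfls[i], p.vfl_within, counts[i])
                start = pd.Timestamp(f"{year}-01-01")
                census = cal.as_index()
                doy = (census - start).days + 1  # day-of-year of censuses
                for k in range(counts[i]):
                    inside = (doy >= onsets[k]) & (doy <= onsets[k] + lengths[k])
                    if not inside.any():
                        n_censored += 1
                        continue
                    obs = census[inside]
                    rows.append({
                        "species": sp, "genus": genus_of[sp],
                        "family": f"{genus_of[sp]}aceae",
                        "life_form": life_form, "year": year,
                        "individual_id": f"{sp}_{year}_{k + 1:03d}",
                        "onset": obs[0], "end": obs[-1]})
    from .records_io import RECORD_COLUMNS
    rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    rec["year"] = rec["year"].astype(int) if len(rec) else rec["year"]
    observed = set(rec["species"])
    for p in param_rows:
        if p["species"] not in observed:
            logger.warning("species %s yielded no observable individuals",
                           p["species"])
    meta = pd.DataFrame(meta_rows)
    meta = meta[meta["species"].isin(rec["species"])].reset_index(drop=True)
    ds = Dataset(records=rec.reset_index(drop=True),
                 calendars=calendars, meta=meta)
    manifest = SimManifest(
        seed=seed, species_params=pd.DataFrame(param_rows),
        n_records=len(rec), n_censored=n_censored,
        config={lf: asdict(p) for lf, p in cfg.items()})
    return ds, manifest


# ----------------------------------------------------------- trees & traits

def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with n_tips extant tips.

    Waiting times between births are Exp(k·birth_rate) while k lineages are
    extant, with a final Exp(n·birth_rate) hold after the last birth, so the
    expected root-to-tip depth is Σ_{k=2}^{n} 1/(k·birth_rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = substream(seed, "yule", n_tips)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    left, right = root.new_child(), root.new_child()
    active = {left: 0.0, right: 0.0}  # node -> birth time
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = list(active)[rng.integers(k)]
        node.edge.length = t - active.pop(node)
        c1, c2 = node.new_child(), node.new_child()
        active[c1] = active[c2] = t
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i, (node, born) in enumerate(active.items()):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"t{i + 1}")
    root.edge.length = None
    return tree


def simulate_bm(tree: dendropy.Tree, sigma2: float = 1.0,
                seed: int = 0) -> dict:
    """Brownian-motion trait: preorder Gaussian increments, root value 0.

    Increment variance is sigma2 × branch length; returns {tip label: value}.
    """
    rng = substream(seed, "bm", sigma2)
    values = {}
    out = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[node] = 0.0
        else:
            b = node.edge.length or 0.0
            inc = rng.normal(0.0, np.sqrt(sigma2 * b)) if sigma2 * b > 0 else 0.0
            values[node] = values[parent] + inc
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out
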
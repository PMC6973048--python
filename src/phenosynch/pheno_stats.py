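"""Species-level phenological variables from individual flowering records.

For each species-year with n observed individuals this module computes:

* TFL  — total flowering length: days from the first individual's onset to
  the last individual's end, inclusive;
* MFL  — mean flowering length of individuals (inclusive day counts);
* VFL  — sample variance (n-1) of individual flowering lengths;
* skewness / kurtosis of the flowering-length distribution (moment
  estimators; kurtosis is non-excess by default, so a normal gives 3);
* onset variance — sample variance of onset days, standardized so the
  first-blooming individual is day 0 (shift-invariant);
* Morisita's aggregation index Iδ over census-date bins, on counts of
  simultaneously flowering individuals.  Larger Iδ = higher intraspecific
  synchrony.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._util import sample_var
from .records_io import CensusCalendar, Dataset

logger = logging.getLogger(__name__)

#: Variables a summary row carries, in output-column order.
VARIABLES = ["TFL", "MFL", "VFL", "skewness_FL", "kurtosis_FL",
             "onset_variance", "morisita_idelta"]


@dataclass
class SpeciesPhenoSummary:
    species: str
    year: object  # int or "pooled"
    n_individuals: int
    TFL: float
    MFL: float
    VFL: float
    skewness_FL: float
    kurtosis_FL: float
    onset_variance: float
    morisita_idelta: float

    def as_dict(self):
        return asdict(self)


def flowering_length(onset, end):
    """Inclusive flowering duration in days: (end - onset) + 1.

    Accepts scalars or aligned array-likes of dates.
    """
    onset = pd.to_datetime(onset)
    end = pd.to_datetime(end)
    delta = (end - onset)
    if isinstance(delta, pd.Series):
        return delta.dt.days.to_numpy() + 1
    if isinstance(delta, pd.TimedeltaIndex):
        return delta.days.to_numpy() + 1
    return int(delta.days) + 1


def total_flowering_length(recs: pd.DataFrame) -> int:
    """TFL: first onset to last end, inclusive, within one species-year."""
    if len(recs) == 0:
        raise ValueError("total_flowering_length needs at least one record")
    return flowering_length(recs["onset"].min(), recs["end"].max())


def onset_offsets(recs: pd.DataFrame) -> np.ndarray:
    """Onset days standardized so the first-blooming individual is 0."""
    onsets = pd.to_datetime(recs["onset"])
    return (onsets - onsets.min()).dt.days.to_numpy()


def _moment_skewness(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.var(x) == 0:
        return float("nan")
    return float(stats.skew(x, bias=True))


def _moment_kurtosis(x: np.ndarray, excess: bool = False) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.var(x) == 0:
        return float("nan")
    return float(stats.kurtosis(x, fisher=excess, bias=True))


def in_flower_counts(recs: pd.DataFrame, calendar: CensusCalendar,
                     bins: str = "season") -> np.ndarray:
    """Counts of individuals in flower at each census date.

    ``bins="season"`` uses every census date of the season (zeros included;
    this is what a census-date × species community table yields and the
    default for Iδ).  ``bins="window"`` restricts to the census dates between
    the species' first onset and last end.
    """
    onset = pd.to_datetime(recs["onset"]).to_numpy()
    end = pd.to_datetime(recs["end"]).to_numpy()
    dates = calendar.as_index().to_numpy()
    if bins == "window":
        dates = dates[(dates >= onset.min()) & (dates <= end.max())]
    elif bins != "season":
        raise ValueError(f"unknown bins mode {bins!r}")
    cover = (onset[:, None] <= dates[None, :]) & (dates[None, :] <= end[:, None])
    return cover.sum(axis=0).astype(int)


def morisita_index(counts) -> float:
    """Morisita's Iδ = q · Σ nᵢ(nᵢ−1) / (N(N−1)) over q time bins.

    Undefined (NaN) when the total count N < 2.  Equals q when all
    individuals co-occur in a single bin; for uniform counts n per bin it is
    q(n−1)/(qn−1) < 1, approaching 1 as n grows.
    """
    n = np.asarray(counts, dtype=float)
    q = n.size
    N = n.sum()
    if N < 2:
        logger.warning("Morisita index undefined: total count %s < 2", N)
        return float("nan")
    return float(q * np.sum(n * (n - 1)) / (N * (N - 1)))


def morisita_from_records(recs: pd.DataFrame, calendar: CensusCalendar,
                          bins: str = "season") -> float:
    if len(recs) < 2:
        return float("nan")
    return morisita_index(in_flower_counts(recs, calendar, bins=bins))


def summarize_species(recs: pd.DataFrame, calendar: CensusCalendar = None,
                      year=None, excess_kurtosis: bool = False,
                      morisita_bins: str = "season") -> SpeciesPhenoSummary:
    """All phenological variables for one species-year's records."""
    if len(recs) == 0:
        raise ValueError("summarize_species needs at least one record")
    species = recs["species"].iloc[0]
    if year is None:
        yrs = recs["year"].unique()
        year = int(yrs[0]) if len(yrs) == 1 else "pooled"
    lengths = flowering_length(recs["onset"], recs["end"]).astype(float)
    idelta = (morisita_from_records(recs, calendar, bins=morisita_bins)
              if calendar is not None else float("nan"))
    return SpeciesPhenoSummary(
        species=species,
        year=year,
        n_individuals=len(recs),
        TFL=float(total_flowering_length(recs)),
        MFL=float(lengths.mean()),
        VFL=sample_var(lengths),
        skewness_FL=_moment_skewness(lengths),
        kurtosis_FL=_moment_kurtosis(lengths, excess=excess_kurtosis),
        onset_variance=sample_var(onset_offsets(recs)),
        morisita_idelta=idelta,
    )


def summarize_dataset(ds: Dataset, per_year: bool = True,
                      morisita_bins: str = "season") -> pd.DataFrame:
    """Summary table, one row per species-year.

    With ``per_year=False`` each species instead gets one "pooled" row whose
    variables are the unweighted mean of its per-year summaries (years are
    replicate seasons; raw records cannot be pooled across calendar years
    without inflating TFL), with n_individuals summed.
    """
    rows = []
    for (sp, yr), grp in ds.records.groupby(["species", "year"], sort=True):
        rows.append(summarize_species(
            grp, ds.calendars[int(yr)], year=int(yr),
            morisita_bins=morisita_bins).as_dict())
    out = pd.DataFrame(rows, columns=["species", "year", "n_individuals",
                                      *VARIABLES])
    if per_year:
        return out
    pooled = out.groupby("species", sort=True).agg(
        {"n_individuals": "sum", **{v: "mean" for v in VARIABLES}})
    pooled.insert(0, "year", "pooled")
    return pooled.reset_index()
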
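"""End-to-end orchestration of the phenology workflow.

run_all sequences: read (or simulate) → species filters → per-species
summaries → year/sample-size mixed models → bootstrap rarefaction +
standardization → life-form comparisons with Holm adjustment → community
synchrony with species-bootstrap CIs → (optionally) phylogenetic signal.
Everything is deterministic given the seeds in the config; per-stage seeds
derive from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_synchrony as cs
from . import group_tests as gt
from . import pheno_stats as ps
from . import rarefaction as rf
from . import records_io as rio
from . import phylo_signal as psig
from . import synthetic_data as sd

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    records: str = None          # paths; records=None -> simulate
    calendar: str = None
    meta: str = None
    tree: str = None             # optional newick for the signal stage
    outdir: str = "phenosynch_out"
    min_individuals: int = 5
    min_days: int = 2
    require_both_years: bool = False
    B: int = 1000
    n_std: tuple = tuple(rf.STANDARD_SIZES)
    alpha: float = 0.05
    seed: int = 0
    pool_years: str = "auto"     # auto | always | never
    phi_denominator: str = "sum_sd"
    morisita_bins: str = "season"
    n_perm: int = 999
    variables: tuple = tuple(ps.VARIABLES)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.pool_years not in ("auto", "always", "never"):
            raise ValueError("pool_years must be auto/always/never")
        if cfg.phi_denominator not in ("sum_sd", "sum_var"):
            raise ValueError("phi_denominator must be sum_sd/sum_var")
        return cfg


def _load(cfg: RunConfig):
    if cfg.records is None:
        ds, _ = sd.simulate_records(seed=cfg.seed)
        return ds
    return rio.read_dataset(cfg.records, cfg.calendar, cfg.meta)


def _year_effect_pool(cfg, summaries, meta) -> dict:
    """Mixed-model year/sample-size screens per variable; decide pooling.

    Gamma GLMM (log link) for positive variables; Gaussian LMM for skewness.
    A variable's years are pooled when the year effect is non-significant.
    """
    merged = summaries.merge(meta[["species", "genus"]], on="species")
    years = sorted(y for y in merged["year"].unique())
    out = {}
    for var in cfg.variables:
        d = merged.dropna(subset=[var]).copy()
        if d.empty or len(d["genus"].unique()) < 2 or len(years) < 2:
            out[var] = {"pool": True, "p_year": float("nan"),
                        "p_n": float("nan")}
            continue
        d["year_c"] = (d["year"] != years[0]).astype(float)
        d["n_obs"] = d["n_individuals"].astype(float)
        try:
            if var == "skewness_FL" or (d[var] <= 0).any():
                res = gt.compare_lmm_models(
                    d.rename(columns={var: "response", "year_c": "year",
                                      "n_obs": "n_observed"}),
                    predictors=("year", "n_observed"))
                p_year = res["tests"]["year"]["p"]
                p_n = res["tests"]["n_observed"]["p"]
            else:
                fit = gt.fit_mixed(d[var].to_numpy(),
                                   d[["year_c", "n_obs"]], d["genus"],
                                   family="gamma")
                p_year = float(fit.pvalues["year_c"])
                p_n = float(fit.pvalues["n_obs"])
        except Exception as err:  # keep the pipeline alive on a bad variable
            logger.warning("year-effect model failed for %s: %s", var, err)
            p_year = p_n = float("nan")
        pool = {"auto": not (p_year < cfg.alpha), "always": True,
                "never": False}[cfg.pool_years]
        out[var] = {"pool": bool(pool), "p_year": p_year, "p_n": p_n}
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run the whole workflow; writes CSV outputs + a JSON run log."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": cfg.seed, "stages": {}}

    def stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    ds = stage("load", lambda: _load(cfg))
    n_in = len(ds.species)
    fds = stage("filter", lambda: rio.filter_species(
        ds, cfg.min_days, cfg.min_individuals, cfg.require_both_years))
    report["stages"]["filter"] = {
        "species_in": n_in, "species_kept": len(fds.species),
        "species_dropped": len(fds.dropped_species)}

    summaries = stage("stats", lambda: ps.summarize_dataset(
        fds, per_year=True, morisita_bins=cfg.morisita_bins))
    rio.write_summary_table(summaries, outdir / "summaries.csv")

    pooling = stage("year_models", lambda: _year_effect_pool(
        cfg, summaries, fds.meta))
    report["stages"]["year_models"] = pooling

    curves = stage("rarefy", lambda: rf.rarefy_dataset(
        fds, variables=cfg.variables, B=cfg.B, seed=cfg.seed,
        morisita_bins=cfg.morisita_bins))
    forms = stage("select_model", lambda: rf.select_models_per_variable(curves))
    report["stages"]["selected_models"] = forms
    std = stage("standardize", lambda: rf.standardize(
        curves, forms, n_std=cfg.n_std))
    std.to_csv(outdir / "standardized.csv", index=False)

    lf_of = dict(zip(fds.meta["species"], fds.meta["life_form"]))
    comp_rows = []
    for var in cfg.variables:
        sv = std[std["variable"] == var].copy()
        if sv.empty:
            continue
        sv["life_form"] = sv["species"].map(lf_of)
        if pooling.get(var, {}).get("pool", True):
            sv = (sv.groupby(["species", "life_form", "n_std"],
                             as_index=False)["value"].mean())
        for n in cfg.n_std:
            one = sv[sv["n_std"] == n]
            groups = {lf: g["value"].to_numpy()
                      for lf, g in one.groupby("life_form")
                      if len(g) >= 3}
            if len(groups) < 2:
                continue
            try:
                t = gt.pairwise_compare(groups, variable=var,
                                        alpha=cfg.alpha)
                t.insert(3, "n_std", n)
                comp_rows.append(t)
            except ValueError as err:
                logger.warning("comparison failed for %s at n=%s: %s",
                               var, n, err)
    comparisons = (pd.concat(comp_rows, ignore_index=True)
                   if comp_rows else pd.DataFrame())
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    sync_rows = []
    for year in fds.years:
        for lf in sorted(fds.records["life_form"].unique()):
            try:
                M = cs.build_matrix(fds, life_form=lf, year=year)
            except ValueError:
                continue
            val = cs.phi(M, denominator=cfg.phi_denominator)
            lo = hi = float("nan")
            if M.shape[1] >= 2:
                lo, hi, _ = cs.phi_ci(M, B=cfg.B, seed=cfg.seed,
                                      denominator=cfg.phi_denominator)
            onsets = cs.species_onsets(fds, life_form=lf, year=year)
            sk = k2 = p = float("nan")
            if len(onsets) >= 8:
                sk, k2, p = cs.onset_skewness_test(onsets)
            slo = shi = float("nan")
            if len(onsets) >= 2:
                slo, shi, _ = cs.skewness_ci(onsets, B=cfg.B, seed=cfg.seed)
            sync_rows.append({
                "year": year, "life_form": lf, "n_species": M.shape[1],
                "phi": val, "phi_ci_low": lo, "phi_ci_high": hi,
                "onset_skewness": sk, "k2": k2, "k2_p": p,
                "skew_ci_low": slo, "skew_ci_high": shi})
    synchrony = pd.DataFrame(sync_rows)
    synchrony.to_csv(outdir / "synchrony.csv", index=False)

    physig = pd.DataFrame()
    if cfg.tree is not None:
        tree = stage("read_tree", lambda: psig.read_newick(cfg.tree))
        tips = set(psig.tip_labels(tree))
        pooled = ps.summarize_dataset(fds, per_year=False)
        rows = []
        for var in cfg.variables:
            trait = {r["species"]: r[var] for _, r in pooled.iterrows()
                     if r["species"] in tips and np.isfinite(r[var])}
            if len(trait) < 4 or set(trait) != tips:
                logger.warning("skipping signal test for %s: trait/tip "
                               "mismatch", var)
                continue
            res = psig.signal_test(tree, trait, n_perm=cfg.n_perm,
                                   seed=cfg.seed)
            rows.append({"variable": var, "K": res.K,
                         "statistic": res.statistic,
                         "p_permutation": res.p_permutation,
                         "n_perm": res.n_perm})
        physig = pd.DataFrame(rows)
        physig.to_csv(outdir / "physig.csv", index=False)

    report["stages"]["outputs"] = sorted(
        p.name for p in outdir.glob("*.csv"))
    report["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(cfg).items()}
    (outdir / "run_log.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
    return {"report": report, "summaries": summaries, "standardized": std,
            "comparisons": comparisons, "synchrony": synchrony,
            "physig": physig, "selected_models": forms}
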
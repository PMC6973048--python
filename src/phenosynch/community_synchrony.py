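"""Interspecific synchrony: community matrices, the φ index, onset-date
skewness, and species-bootstrap confidence intervals.

The community-wide synchrony index of Loreau & de Mazancourt (2008) is

    φ = Var_t[x_T(t)] / ( Σ_i SD_t[x_i(t)] )²

where x_i(t) is the number of individuals of species i in flower at census
date t and x_T(t) = Σ_i x_i(t).  φ = 1 for perfectly synchronous (identical
up to scale) series and ≈ 1/S for S independent series of equal variance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._util import substream
from .records_io import Dataset

logger = logging.getLogger(__name__)


def build_matrix(ds: Dataset, life_form: str = None,
                 year: int = None) -> pd.DataFrame:
    """Census-date × species counts of simultaneously flowering individuals.

    Rows are the full season calendar of ``year``; columns are the species of
    the requested life form.
    """
    rec = ds.records
    if year is not None:
        rec = rec[rec["year"] == year]
    if life_form is not None:
        rec = rec[rec["life_form"] == life_form]
    if len(rec) == 0:
        raise ValueError(f"no records for life_form={life_form!r}, "
                         f"year={year!r}")
    years = rec["year"].unique()
    if len(years) != 1:
        raise ValueError("build_matrix needs a single year")
    cal = ds.calendars[int(years[0])]
    dates = cal.as_index()
    cols = {}
    for sp, grp in rec.groupby("species", sort=True):
        onset = pd.to_datetime(grp["onset"]).to_numpy()
        end = pd.to_datetime(grp["end"]).to_numpy()
        d = dates.to_numpy()
        cover = (onset[:, None] <= d[None, :]) & (d[None, :] <= end[:, None])
        cols[sp] = cover.sum(axis=0)
    return pd.DataFrame(cols, index=dates)


def phi(M, denominator: str = "sum_sd", ddof: int = 1) -> float:
    """Community-wide synchrony index of a census-date × species matrix.

    ``denominator="sum_sd"`` is the Loreau–de Mazancourt definition
    (squared sum of per-species temporal SDs); ``"sum_var"`` is the literal
    sum-of-variances variant kept for sensitivity checks.  NaN (with a
    warning) when every series is constant.
    """
    X = np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("phi needs a (time × species) matrix with >=2 rows")
    var_T = X.sum(axis=1).var(ddof=ddof)
    sds = X.std(axis=0, ddof=ddof)
    if denominator == "sum_sd":
        denom = sds.sum() ** 2
    elif denominator == "sum_var":
        denom = (sds ** 2).sum()
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        logger.warning("phi undefined: all species series are constant")
        return float("nan")
    return float(var_T / denom)


def species_onsets(ds: Dataset, life_form: str = None,
                   year: int = None) -> pd.Series:
    """Species-level onset day-of-year: earliest individual onset."""
    rec = ds.records
    if year is not None:
        rec = rec[rec["year"] == year]
    if life_form is not None:
        rec = rec[rec["life_form"] == life_form]
    if len(rec) == 0:
        raise ValueError("no records in the requested group")
    onset = rec.groupby("species", sort=True)["onset"].min()
    return onset.dt.dayofyear.astype(float)


def onset_skewness_test(onsets) -> tuple:
    """Moment skewness of onset days plus the D'Agostino–Pearson omnibus K².

    Returns (skewness, K², p) with p from χ²(2).  Requires n >= 8 for the
    validity of the skewness/kurtosis z-transformations.
    """
    x = np.asarray(onsets, dtype=float)
    if x.size < 8:
        raise ValueError(f"D'Agostino's K² needs n >= 8, got {x.size}")
    if np.var(x) == 0:
        logger.warning("onset skewness undefined: zero variance")
        return float("nan"), float("nan"), float("nan")
    skew = float(stats.skew(x, bias=True))
    k2, p = stats.normaltest(x)
    return skew, float(k2), float(p)


def bootstrap_group_ci(items, stat_fn, B: int = 1000, seed: int = 0,
                       level: float = 0.95) -> tuple:
    """Percentile CI of a group statistic under species-level resampling.

    ``items`` is the per-species collection (e.g. the columns of a community
    matrix, or per-species onsets); each replicate resamples species with
    replacement at the group's own size and applies ``stat_fn`` to the
    resampled collection.  Replicates where the statistic is undefined are
    dropped; returns (lo, hi, effective_B).
    """
    n = len(items)
    if n < 2:
        raise ValueError("bootstrap needs >=2 species")
    rng = substream(seed, "group_ci", B)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        v = stat_fn([items[i] for i in idx])
        if np.isfinite(v):
            vals.append(v)
    eff = len(vals)
    if eff == 0:
        logger.warning("statistic undefined in every bootstrap replicate")
        return float("nan"), float("nan"), 0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi), eff


def phi_ci(M: pd.DataFrame, B: int = 1000, seed: int = 0,
           denominator: str = "sum_sd") -> tuple:
    """95% species-bootstrap CI of φ for one community matrix."""
    series = [M.iloc[:, i].to_numpy() for i in range(M.shape[1])]
    return bootstrap_group_ci(
        series, lambda cols: phi(np.column_stack(cols),
                                 denominator=denominator),
        B=B, seed=seed)


def skewness_ci(onsets, B: int = 1000, seed: int = 0) -> tuple:
    """95% species-bootstrap CI of onset-date skewness for one group."""
    vals = list(np.asarray(onsets, dtype=float))
    def _sk(sub):
        a = np.asarray(sub, dtype=float)
        if np.var(a) == 0:
            return float("nan")
        return float(stats.skew(a, bias=True))
    return bootstrap_group_ci(vals, _sk, B=B, seed=seed)
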
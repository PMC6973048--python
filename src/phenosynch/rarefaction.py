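"""Bootstrap rarefaction–extrapolation of phenological variables.

For each species and variable, the expected value of the statistic at sample
size j is estimated by resampling j individuals with replacement B times and
averaging (replicates where the statistic is undefined are dropped).  The
resulting curves, pooled across species after rescaling each by its own
maximum, drive a four-model comparison (linear, quadratic, logarithmic,
3-parameter logistic) by BIC; the winning form is then fitted to each
species' raw curve and evaluated at standardized sample sizes, interpolating
or extrapolating as needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import substream
from .pheno_stats import VARIABLES, flowering_length, in_flower_counts
from .records_io import CensusCalendar, Dataset

logger = logging.getLogger(__name__)

#: Minimum sample size at which each statistic is defined.
_MIN_N = {"TFL": 1, "MFL": 1, "VFL": 2, "onset_variance": 2,
          "morisita_idelta": 2, "skewness_FL": 3, "kurtosis_FL": 4}

#: Fixed tie-break order: fewest parameters first, then this sequence.
MODEL_FORMS = ("linear", "logarithmic", "quadratic", "logistic")
_N_PARAMS = {"linear": 2, "logarithmic": 2, "quadratic": 3, "logistic": 3}

STANDARD_SIZES = (5, 7, 12, 18, 22)


@dataclass
class BootstrapCurve:
    species: str
    year: object
    variable: str
    sizes: np.ndarray
    means: np.ndarray
    effective_B: np.ndarray
    B: int
    seed: int


@dataclass
class CandidateModelFit:
    form: str
    params: np.ndarray
    rss: float
    bic: float


@dataclass
class StandardizedEstimate:
    species: str
    year: object
    variable: str
    n_std: int
    value: float


def _replicate_stats(variable, idx, lengths, onset_days, end_days, cover):
    """Statistic per bootstrap draw; idx is a (B, j) index matrix."""
    j = idx.shape[1]
    if variable == "TFL":
        return end_days[idx].max(axis=1) - onset_days[idx].min(axis=1) + 1.0
    if variable == "MFL":
        return lengths[idx].mean(axis=1)
    if variable == "VFL":
        return lengths[idx].var(axis=1, ddof=1)
    if variable == "onset_variance":
        return onset_days[idx].var(axis=1, ddof=1)
    if variable in ("skewness_FL", "kurtosis_FL"):
        x = lengths[idx]
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-constant draws -> NaN
            if variable == "skewness_FL":
                v = stats.skew(x, axis=1, bias=True)
            else:
                v = stats.kurtosis(x, axis=1, fisher=False, bias=True)
        v = np.asarray(v, dtype=float)
        v[x.var(axis=1) == 0] = np.nan  # moment ratio undefined
        return v
    if variable == "morisita_idelta":
        counts = cover[idx].sum(axis=1).astype(float)  # (B, q)
        N = counts.sum(axis=1)
        num = (counts * (counts - 1)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = counts.shape[1] * num / (N * (N - 1))
        v[N < 2] = np.nan
        return v
    raise ValueError(f"unknown variable {variable!r}")


def bootstrap_curve(recs: pd.DataFrame, variable: str,
                    calendar: CensusCalendar = None, n_max: int = None,
                    B: int = 1000, seed: int = 0,
                    morisita_bins: str = "season") -> BootstrapCurve:
    """Rarefaction curve of one variable for one species-year.

    Sample sizes run from the statistic's minimum up to ``n_max`` (default:
    the species' own number of observed individuals).  Reproducible: the RNG
    substream is derived from (seed, species, variable).
    """
    if len(recs) < 1:
        raise ValueError("bootstrap_curve needs at least one individual")
    species = recs["species"].iloc[0]
    yrs = recs["year"].unique()
    year = int(yrs[0]) if len(yrs) == 1 else "pooled"
    n = len(recs)
    if n_max is None:
        n_max = n
    lengths = flowering_length(recs["onset"], recs["end"]).astype(float)
    onsets = pd.to_datetime(recs["onset"])
    onset_days = (onsets - onsets.min()).dt.days.to_numpy().astype(float)
    end_days = onset_days + lengths - 1.0
    cover = None
    if variable == "morisita_idelta":
        if calendar is None:
            raise ValueError("morisita_idelta needs a census calendar")
        onset_np = onsets.to_numpy()
        end_np = pd.to_datetime(recs["end"]).to_numpy()
        dates = calendar.as_index().to_numpy()
        if morisita_bins == "window":
            dates = dates[(dates >= onset_np.min()) & (dates <= end_np.max())]
        cover = ((onset_np[:, None] <= dates[None, :])
                 & (dates[None, :] <= end_np[:, None]))

    rng = substream(seed, species, year, variable)
    sizes, means, eff = [], [], []
    for j in range(_MIN_N[variable], n_max + 1):
        idx = rng.integers(0, n, size=(B, j))
        vals = _replicate_stats(variable, idx, lengths, onset_days,
                                end_days, cover)
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        sizes.append(j)
        means.append(float(vals[ok].mean()))
        eff.append(int(ok.sum()))
    if not sizes:
        logger.warning("%s %s: statistic undefined at every sample size",
                       species, variable)
    return BootstrapCurve(species, year, variable, np.asarray(sizes),
                          np.asarray(means), np.asarray(eff), B, seed)


def rarefy_dataset(ds: Dataset, variables=VARIABLES, n_max: int = None,
                   B: int = 1000, seed: int = 0,
                   morisita_bins: str = "season") -> list:
    """Curves for every species-year and variable in the dataset."""
    curves = []
    for (sp, yr), grp in ds.records.groupby(["species", "year"], sort=True):
        for var in variables:
            c = bootstrap_curve(grp, var, calendar=ds.calendars[int(yr)],
                                n_max=n_max, B=B, seed=seed,
                                morisita_bins=morisita_bins)
            if len(c.sizes):
                curves.append(c)
    return curves


# ---------------------------------------------------------------- model fits

def _design(form, x):
    if form == "linear":
        return np.column_stack([np.ones_like(x), x])
    if form == "quadratic":
        return np.column_stack([np.ones_like(x), x, x ** 2])
    if form == "logarithmic":
        return np.column_stack([np.ones_like(x), np.log(x)])
    raise ValueError(form)


def _logistic(x, a, b, c):
    return a / (1.0 + np.exp(-b * (x - c)))


def fit_form(form: str, x: np.ndarray, y: np.ndarray) -> CandidateModelFit:
    """Least-squares fit of one candidate form; BIC = m·ln(RSS/m) + k·ln m
    with k = mean-function parameters + 1 (error variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = len(x)
    if form == "logistic":
        a0 = float(np.max(y))
        if a0 <= 0:
            a0 = max(abs(a0), 1e-6)
        half = a0 / 2.0
        c0 = float(x[np.argmin(np.abs(y - half))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, _ = optimize.curve_fit(
                _logistic, x, y, p0=[a0, 1.0, c0],
                bounds=([1e-12, -50.0, -np.inf], [np.inf, 50.0, np.inf]),
                maxfev=500 * 4)
        resid = y - _logistic(x, *params)
    else:
        X = _design(form, x)
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ params
    rss = float(resid @ resid)
    # exact fits leave only rounding noise in RSS; clamp to a common floor so
    # parsimony (not machine noise) breaks the tie between them
    floor = m * (1e-9 * max(1.0, float(np.abs(y).max()))) ** 2
    k = _N_PARAMS[form] + 1
    bic = m * np.log(max(rss, floor) / m) + k * np.log(m)
    return CandidateModelFit(form, np.asarray(params), rss, float(bic))


def predict_form(form: str, params: np.ndarray, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if form == "logistic":
        return _logistic(x, *params)
    return _design(form, x) @ params


def select_model(curves: list) -> tuple:
    """BIC model selection on the pooled, per-species max-rescaled curves.

    Returns (winning form name, list of CandidateModelFit).  Ties go to the
    model with fewer parameters, then to the fixed order linear <
    logarithmic < quadratic < logistic.
    """
    xs, ys = [], []
    for c in curves:
        top = np.nanmax(c.means)
        if not np.isfinite(top) or top == 0:
            logger.warning("skipping %s %s in pooled selection: "
                           "max %s", c.species, c.variable, top)
            continue
        xs.append(c.sizes)
        ys.append(c.means / top)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    fits = []
    for form in MODEL_FORMS:
        try:
            fits.append(fit_form(form, x, y))
        except (RuntimeError, ValueError) as err:
            logger.warning("%s fit failed in model selection: %s", form, err)
    order = {f: i for i, f in enumerate(MODEL_FORMS)}
    best = min(fits, key=lambda f: (f.bic, _N_PARAMS[f.form], order[f.form]))
    return best.form, fits


def standardized_value(curve: BootstrapCurve, form: str,
                       n_std: int) -> StandardizedEstimate:
    """Fitted value of the selected form at a standardized sample size.

    The form is fitted to the species' own raw curve; if the fit fails the
    bootstrap mean at the nearest available sample size is used instead.
    """
    try:
        fit = fit_form(form, curve.sizes, curve.means)
        val = float(predict_form(form, fit.params, [n_std])[0])
        if not np.isfinite(val):
            raise ValueError("non-finite prediction")
    except (RuntimeError, ValueError) as err:
        ok = np.isfinite(curve.means)
        nearest = int(np.flatnonzero(ok)[
            np.argmin(np.abs(curve.sizes[ok] - n_std))])
        val = float(curve.means[nearest])
        logger.warning("%s %s: %s fit failed (%s); using bootstrap mean at "
                       "j=%d", curve.species, curve.variable, form, err,
                       curve.sizes[nearest])
    return StandardizedEstimate(curve.species, curve.year, curve.variable,
                                int(n_std), val)


def standardize(curves: list, selected_forms: dict,
                n_std=STANDARD_SIZES) -> pd.DataFrame:
    """Evaluate every curve at the standardized sizes using the globally
    selected form for its variable."""
    rows = []
    for c in curves:
        form = selected_forms[c.variable]
        for n in n_std:
            est = standardized_value(c, form, n)
            rows.append({"species": est.species, "year": est.year,
                         "variable": est.variable, "n_std": est.n_std,
                         "value": est.value, "form": form})
    return pd.DataFrame(rows)


def select_models_per_variable(curves: list) -> dict:
    """Run pooled BIC selection separately for each variable present."""
    by_var = {}
    for c in curves:
        by_var.setdefault(c.variable, []).append(c)
    return {var: select_model(cs)[0] for var, cs in by_var.items()}
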
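"""Life-form comparisons: data-driven two-sample test selection, the
Fligner–Policello robust rank-order test, Holm adjustment, and mixed models
with a genus random intercept.

Test selection follows the decision rule: Student's t when both samples pass
Shapiro–Wilk normality; Wilcoxon rank-sum when normality fails but
median-centred Levene finds homogeneous variances; Fligner–Policello when
both normality and variance homogeneity fail.

The gamma GLMM (log link, genus random intercept) is fitted by
Laplace-approximated maximum likelihood: the one-dimensional random-effect
mode per genus is found by Newton's method and the marginal likelihood
approximated analytically, then the fixed effects, gamma shape and
random-intercept variance are optimised jointly.  The Gaussian case
delegates to statsmodels' MixedLM with full ML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess

logger = logging.getLogger(__name__)

TESTS = ("t", "wilcoxon", "fligner_policello")


# ------------------------------------------------------------ rank machinery

def select_test(x, y, alpha: float = 0.05) -> str:
    """Choose t / wilcoxon / fligner_policello from the two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("select_test needs n >= 3 in each sample")
    normal = (stats.shapiro(x).pvalue >= alpha
              and stats.shapiro(y).pvalue >= alpha)
    if normal:
        return "t"
    equal_var = stats.levene(x, y, center="median").pvalue >= alpha
    return "wilcoxon" if equal_var else "fligner_policello"


def fligner_policello(x, y) -> tuple:
    """Fligner–Policello robust rank-order test (two-sided).

    Placements P_i = #{y_j < x_i} (+½ per tie) and the mirror Q_j; the
    statistic is U = (ΣP − ΣQ) / (2·√(V1 + V2 + P̄·Q̄)) with V the placement
    sums of squares, referred to a standard normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("fligner_policello needs n >= 3 in each sample")
    if np.all(np.concatenate([x, y]) == x[0]):
        raise ValueError("all values tied: statistic undefined")
    P = (y[None, :] < x[:, None]).sum(axis=1) + 0.5 * (
        y[None, :] == x[:, None]).sum(axis=1)
    Q = (x[None, :] < y[:, None]).sum(axis=1) + 0.5 * (
        x[None, :] == y[:, None]).sum(axis=1)
    Pbar, Qbar = P.mean(), Q.mean()
    V1 = ((P - Pbar) ** 2).sum()
    V2 = ((Q - Qbar) ** 2).sum()
    denom = 2.0 * np.sqrt(V1 + V2 + Pbar * Qbar)
    if denom == 0:
        # complete separation with zero placement variance: evidence is
        # maximal, report an infinite statistic rather than 0/0
        return float(np.sign(P.sum() - Q.sum()) * np.inf), 0.0
    U = (P.sum() - Q.sum()) / denom
    p = 2.0 * stats.norm.sf(abs(U))
    return float(U), float(min(p, 1.0))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_test(x, y, test: str) -> tuple:
    """Apply a chosen two-sample test; returns (statistic, p two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "t":
        r = stats.ttest_ind(x, y, equal_var=True)
        return float(r.statistic), float(r.pvalue)
    if test == "wilcoxon":
        r = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(r.statistic), float(r.pvalue)
    if test == "fligner_policello":
        return fligner_policello(x, y)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class PairwiseComparison:
    pair: tuple
    variable: str
    test_used: str
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")


def pairwise_compare(groups: dict, variable: str = "",
                     alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise two-sample comparisons among named groups.

    Test selection is per pair; Holm adjustment is applied across the pairs
    compared in this call.
    """
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            test = select_test(groups[a], groups[b], alpha=alpha)
            statistic, p = run_test(groups[a], groups[b], test)
            rows.append(PairwiseComparison((a, b), variable, test,
                                           statistic, p))
    padj = holm_adjust([r.p_raw for r in rows])
    for r, q in zip(rows, padj):
        r.p_adjusted = float(q)
    return pd.DataFrame([{
        "group_a": r.pair[0], "group_b": r.pair[1], "variable": r.variable,
        "test_used": r.test_used, "statistic": r.statistic,
        "p_raw": r.p_raw, "p_adjusted": r.p_adjusted} for r in rows])


# ------------------------------------------------------------- mixed models

@dataclass
class MixedModelFit:
    family: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    random_variance: float
    loglik: float
    shape: float = float("nan")  # gamma shape (1/dispersion)
    converged: bool = True
    warnings: list = field(default_factory=list)


def _gamma_loglik_terms(y, eta, u, alpha):
    mu_log = eta + u
    return (alpha * np.log(alpha) - alpha * mu_log + (alpha - 1) * np.log(y)
            - alpha * y * np.exp(-mu_log) - special.gammaln(alpha))


def _group_mode(S, n_g, alpha, sigma2, tol=1e-10, maxit=100):
    """Newton mode of the random-intercept conditional posterior.

    Solves alpha*(S*exp(-u) - n_g) - u/sigma2 = 0 (strictly concave).
    """
    u = 0.0
    for _ in range(maxit):
        g = alpha * (S * np.exp(-u) - n_g) - u / sigma2
        h = -alpha * S * np.exp(-u) - 1.0 / sigma2
        step = g / h
        u -= step
        if abs(step) < tol:
            break
    return u


def _gamma_laplace_nll(theta, y, X, group_idx, n_groups):
    p = X.shape[1]
    beta = theta[:p]
    alpha = np.exp(theta[p])
    sigma2 = theta[p + 1]
    eta = X @ beta
    w = y * np.exp(-eta)
    nll = 0.0
    for g in range(n_groups):
        sel = group_idx == g
        S = w[sel].sum()
        n_g = sel.sum()
        if sigma2 <= 1e-12:
            u = 0.0
            corr = 0.0
        else:
            u = _group_mode(S, n_g, alpha, sigma2)
            corr = 0.5 * np.log1p(sigma2 * alpha * S * np.exp(-u))
        ll = _gamma_loglik_terms(y[sel], eta[sel], u, alpha).sum()
        if sigma2 > 1e-12:
            ll -= u * u / (2.0 * sigma2)
        nll -= ll - corr
    return nll


def _fit_gamma_glmm(y, X, groups):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma family requires strictly positive responses")
    Xm = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = codes.max() + 1
    p = Xm.shape[1]

    glm = sm.GLM(y, Xm, family=sm.families.Gamma(sm.families.links.Log()))
    glm_res = glm.fit()
    alpha0 = 1.0 / max(glm_res.scale, 1e-6)
    theta0 = np.concatenate([glm_res.params, [np.log(alpha0)], [0.1]])

    bounds = [(None, None)] * p + [(-10.0, 15.0), (0.0, None)]
    obj = lambda th: _gamma_laplace_nll(th, y, Xm, codes, n_groups)
    res = optimize.minimize(obj, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-8})
    # restart from the GLM solution with tiny variance if the first try
    # stalled; Laplace surfaces can be flat in sigma2 near zero
    if not res.success:
        theta1 = np.concatenate([glm_res.params, [np.log(alpha0)], [1e-4]])
        res2 = optimize.minimize(obj, theta1, method="L-BFGS-B",
                                 bounds=bounds,
                                 options={"maxiter": 500, "ftol": 1e-12})
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    sigma2 = float(theta[p + 1])
    warns = []
    if sigma2 <= 1e-10:
        warns.append("singular fit: random-intercept variance at zero")
        logger.warning(warns[-1])

    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(p)])
    # Wald covariance from the numeric Hessian of the Laplace deviance;
    # fall back to the GLM covariance if it is not invertible
    try:
        H = approx_hess(theta, obj)
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except Exception:  # pragma: no cover - numerical edge
        se = glm_res.bse
    z = theta[:p] / np.where(se > 0, se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return MixedModelFit(
        family="gamma_log",
        params=pd.Series(theta[:p], index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        random_variance=sigma2,
        loglik=float(-res.fun),
        shape=float(np.exp(theta[p])),
        converged=bool(res.success),
        warnings=warns,
    )


def _fit_gaussian_lmm(y, X, groups):
    Xm = pd.DataFrame(np.asarray(X, dtype=float),
                      columns=(list(X.columns) if isinstance(X, pd.DataFrame)
                               else None))
    model = sm.MixedLM(np.asarray(y, dtype=float), Xm,
                       groups=np.asarray(groups))
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        # best-of-restarts: optimizers occasionally under-fit the profiled
        # likelihood, which would bias downstream likelihood-ratio tests
        res = model.fit(reml=False)
        try:
            alt = model.fit(reml=False, method="lbfgs")
            if np.isfinite(alt.llf) and alt.llf > res.llf:
                res = alt
        except Exception:
            pass
    var_u = float(res.cov_re.iloc[0, 0])
    warns = []
    if var_u <= 1e-10:
        warns.append("singular fit: random-intercept variance at zero")
    k = len(res.fe_params)
    return MixedModelFit(
        family="gaussian_identity",
        params=pd.Series(np.asarray(res.fe_params),
                         index=list(Xm.columns)[:k]),
        bse=pd.Series(np.asarray(res.bse)[:k], index=list(Xm.columns)[:k]),
        pvalues=pd.Series(np.asarray(res.pvalues)[:k],
                          index=list(Xm.columns)[:k]),
        random_variance=var_u,
        loglik=float(res.llf),
        converged=bool(res.converged),
        warnings=warns,
    )


def fit_mixed(response, fixed, groups, family: str = "gamma") -> MixedModelFit:
    """Random-intercept mixed model of per-species phenology values.

    Parameters
    ----------
    response : array-like
        Per species(-year) variable values; strictly positive for gamma.
    fixed : DataFrame or 2-d array
        Fixed-effect design matrix *without* intercept; one is prepended.
    groups : array-like
        Genus labels defining the random intercept.
    family : {"gamma", "gaussian"}
        Gamma with log link (Laplace ML) or Gaussian identity (profile ML).
    """
    fixed = pd.DataFrame(fixed).copy() if fixed is not None else pd.DataFrame(
        index=range(len(response)))
    fixed.insert(0, "Intercept", 1.0)
    if family == "gamma":
        return _fit_gamma_glmm(response, fixed, groups)
    if family == "gaussian":
        return _fit_gaussian_lmm(response, fixed, groups)
    raise ValueError(f"unknown family {family!r}")


def compare_lmm_models(data: pd.DataFrame, response: str = "response",
                       genus: str = "genus",
                       predictors: tuple = ("year", "n_observed")) -> dict:
    """Likelihood-ratio tests of the skewness LMM ladder.

    Model 0: random intercept only.  Each model k adds one predictor.  All
    fits use full ML on the identical rows; returns per-predictor LRT
    statistics and chi-square(1) p values plus the log-likelihoods.
    """
    df = data.dropna(subset=[response, genus, *predictors])
    y = df[response].to_numpy(dtype=float)
    g = df[genus].to_numpy()
    base = fit_mixed(y, None, g, family="gaussian")
    out = {"loglik_null": base.loglik, "tests": {}}
    for pred in predictors:
        X = df[[pred]].astype(float)
        fit = fit_mixed(y, X, g, family="gaussian")
        lrt = max(2.0 * (fit.loglik - base.loglik), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        out["tests"][pred] = {"lrt": float(lrt), "p": p,
                              "loglik": fit.loglik,
                              "estimate": float(fit.params[pred])}
    return out
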
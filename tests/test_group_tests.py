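"""Two-sample test selection, Fligner–Policello, Holm, mixed models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenosynch import group_tests as gt


class TestSelectTest:
    def test_gaussian_pair_gets_t(self):
        rng = np.random.default_rng(0)
        assert gt.select_test(rng.normal(0, 1, 80),
                              rng.normal(0.3, 1, 80)) == "t"

    def test_lognormal_equal_scale_gets_wilcoxon(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, 60)
        y = rng.lognormal(0.2, 1, 60)
        assert gt.select_test(x, y) == "wilcoxon"

    def test_lognormal_scale_difference_gets_fligner_policello(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, 60)
        y = 10.0 * rng.lognormal(0, 1, 60)
        assert gt.select_test(x, y) == "fligner_policello"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            gt.select_test([1.0, 2.0], [3.0, 4.0, 5.0])

    def test_pure_function(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.exponential(1, 20)
        assert gt.select_test(x, y) == gt.select_test(x, y)


def fp_oracle(x, y):
    """Loop-based placement computation, independent of the vectorized path."""
    P = []
    for xi in x:
        P.append(sum(1.0 for yj in y if yj < xi)
                 + 0.5 * sum(1.0 for yj in y if yj == xi))
    Q = []
    for yj in y:
        Q.append(sum(1.0 for xi in x if xi < yj)
                 + 0.5 * sum(1.0 for xi in x if xi == yj))
    Pb, Qb = np.mean(P), np.mean(Q)
    V1 = sum((p - Pb) ** 2 for p in P)
    V2 = sum((q - Qb) ** 2 for q in Q)
    denom = 2 * np.sqrt(V1 + V2 + Pb * Qb)
    if denom == 0:
        return np.sign(sum(P) - sum(Q)) * np.inf, 0.0
    U = (sum(P) - sum(Q)) / denom
    return U, min(2 * stats.norm.sf(abs(U)), 1.0)


class TestFlignerPolicello:
    def test_identical_samples_symmetric(self):
        x = np.array([1., 2., 3., 4., 5.])
        U, p = gt.fligner_policello(x, x)
        assert U == 0 and p == 1

    def test_complete_separation_matches_oracle(self):
        x = np.array([10., 11., 12., 13., 14.])
        y = np.array([1., 2., 3., 4., 5.])
        U, p = gt.fligner_policello(x, y)
        Uo, po = fp_oracle(x, y)
        assert U == pytest.approx(Uo, abs=1e-12)
        assert U > 0 and p == pytest.approx(po, abs=1e-12)

    def test_matches_oracle_on_random_samples(self):
        rng = np.random.default_rng(4)
        for nx in range(3, 7):
            for ny in range(3, 7):
                for rep in range(5):
                    x = np.round(rng.normal(0, 1, nx), 1)  # induce ties
                    y = np.round(rng.normal(0.5, 2, ny), 1)
                    U, p = gt.fligner_policello(x, y)
                    Uo, po = fp_oracle(x, y)
                    assert U == Uo or abs(U - Uo) < 1e-12
                    assert p == pytest.approx(po, abs=1e-12)

    def test_antisymmetric_in_samples(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 11)
        U1, p1 = gt.fligner_policello(x, y)
        U2, p2 = gt.fligner_policello(y, x)
        assert U1 == pytest.approx(-U2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            gt.fligner_policello([2., 2., 2.], [2., 2., 2.])


class TestHolm:
    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(gt.holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert gt.holm_adjust([0.2]) == pytest.approx([0.2])

    def test_cap_and_cummax(self):
        np.testing.assert_allclose(gt.holm_adjust([0.5, 0.9]), [1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            gt.holm_adjust([0.1, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            ours = gt.holm_adjust(p)
            theirs = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
    @settings(max_examples=80, deadline=None)
    def test_pointwise_dominance_and_equivariance(self, p):
        adj = gt.holm_adjust(p)
        assert np.all(adj >= np.asarray(p))
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = gt.holm_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-15)


class TestPairwiseCompare:
    def test_three_groups_three_rows_holm_adjusted(self):
        rng = np.random.default_rng(7)
        groups = {"tree": rng.normal(0, 1, 15),
                  "perennial": rng.normal(1, 1, 15),
                  "annual": rng.normal(2, 1, 15)}
        out = gt.pairwise_compare(groups, variable="TFL")
        assert len(out) == 3
        assert np.all(out["p_adjusted"] >= out["p_raw"] - 1e-15)
        np.testing.assert_allclose(out["p_adjusted"],
                                   gt.holm_adjust(out["p_raw"]))


class TestGammaGLMM:
    def test_zero_genus_variance_matches_plain_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(0, 1, n)
        y = rng.gamma(5.0, np.exp(1.0 + 0.5 * x) / 5.0)
        genus = np.repeat(np.arange(20), 10)
        fit = gt.fit_mixed(y, pd.DataFrame({"x": x}), genus, family="gamma")
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        rel = np.abs(fit.params.to_numpy() - np.asarray(glm.params)) \
            / np.abs(np.asarray(glm.params))
        assert np.all(rel < 1e-3)
        assert fit.random_variance < 0.01

    def test_slope_recovery_with_genus_effects(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(0, 1, n)
        genera = np.repeat(np.arange(20), 20)
        u = rng.normal(0, 0.4, 20)
        y = rng.gamma(4.0, np.exp(1.0 + 0.5 * x + u[genera]) / 4.0)
        fit = gt.fit_mixed(y, pd.DataFrame({"x": x}), genera, family="gamma")
        assert fit.params["x"] == pytest.approx(0.5, abs=0.1)
        assert fit.random_variance > 0

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gt.fit_mixed(np.array([1.0, -2.0, 3.0]), None,
                         np.array([0, 0, 1]), family="gamma")


class TestGaussianLMM:
    def test_balanced_design_matches_ml_closed_forms(self):
        # balanced one-way random design: profile ML gives
        # sigma_e^2 = MSW, sigma_u^2 = ((g-1)/g * MSB - MSW) / n
        rng = np.random.default_rng(3)
        g, n = 12, 8
        u = rng.normal(0, 2.0, g)
        y = (5 + u[:, None] + rng.normal(0, 1.5, (g, n))).ravel()
        groups = np.repeat(np.arange(g), n)
        fit = gt.fit_mixed(y, None, groups, family="gaussian")
        yb_i = y.reshape(g, n).mean(1)
        MSW = ((y.reshape(g, n) - yb_i[:, None]) ** 2).sum() / (g * (n - 1))
        MSB = n * ((yb_i - y.mean()) ** 2).sum() / (g - 1)
        sig_u = ((g - 1) / g * MSB - MSW) / n
        assert fit.random_variance == pytest.approx(sig_u, abs=1e-4)

    def test_lrt_ladder(self):
        rng = np.random.default_rng(13)
        genera = np.repeat(np.arange(15), 3)[:43]
        u = rng.normal(0, 0.5, 15)
        rows = []
        for sp in range(43):
            for yr in (0.0, 1.0):
                rows.append((u[genera[sp]] + 0.9 * yr + rng.normal(0, 1),
                             yr, rng.normal(15, 4), genera[sp]))
        df = pd.DataFrame(rows, columns=["response", "year", "n_observed",
                                         "genus"])
        res = gt.compare_lmm_models(df)
        assert res["tests"]["year"]["lrt"] >= 0
        assert res["tests"]["n_observed"]["lrt"] >= 0
        assert res["tests"]["year"]["p"] < 0.05       # strong simulated effect
        assert res["tests"]["n_observed"]["p"] > 0.05  # no simulated effect
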
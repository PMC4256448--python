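"""NB-GLM fitting, dispersion estimation, LRT contrasts, BH adjustment,
and log-fold-change clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from plasmamir.nbglm import (
    adjust_bh,
    build_designs,
    estimate_dispersions,
    fit_nb_glm,
    fit_nb_glm_many,
    logfc_cluster,
    lrt_contrast,
    nb_loglik,
    run_differential,
)
from plasmamir.simulate import simulate_counts


class TestFit:
    def test_intercept_only_poisson_mle_is_log_mean(self):
        fit = fit_nb_glm([3, 5, 7, 9], np.ones((4, 1)), np.zeros(4), 0.0)
        assert fit.beta[0, 0] == pytest.approx(np.log(6), abs=1e-10)

    def test_offset_shift_moves_only_intercept(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(8), rng.integers(0, 2, 8).astype(float)])
        y = rng.poisson(20, 8)
        o = np.zeros(8)
        f1 = fit_nb_glm(y, X, o, 0.1)
        f2 = fit_nb_glm(y, X, o + np.log(2), 0.1)
        assert f2.beta[0, 0] == pytest.approx(f1.beta[0, 0] - np.log(2), abs=1e-8)
        assert f2.beta[0, 1] == pytest.approx(f1.beta[0, 1], abs=1e-8)

    def test_loglik_matches_direct_numerical_maximization(self):
        """IRLS log-likelihood == generic-optimizer maximum within 1e-6."""
        rng = np.random.default_rng(5)
        n = 12
        X = np.column_stack(
            [np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)]
        ).astype(float)
        o = rng.normal(8, 0.3, n)
        phi = 0.3
        for _ in range(20):
            beta = np.array([-4.5, rng.normal(0, 0.5), rng.normal(0, 0.5)])
            mu = np.exp(X @ beta + o)
            r = 1 / phi
            y = rng.negative_binomial(r, r / (r + mu)).astype(float)
            if y.sum() == 0:
                continue
            fit = fit_nb_glm(y, X, o, phi)

            def nll(b):
                return -nb_loglik(y, np.exp(np.clip(X @ b + o, -30, 30)), phi)[0]

            res = minimize(nll, fit.beta[0] + 0.25, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 20000})
            assert fit.loglik[0] >= -res.fun - 1e-6

    def test_all_zero_feature_flagged_with_zero_mean_limit(self):
        fit = fit_nb_glm(np.zeros(6), np.ones((6, 1)), np.zeros(6), 0.2)
        assert fit.zero_fitted[0]
        assert fit.mu.max() < 1e-8

    def test_collinear_design_raises(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="full rank"):
            fit_nb_glm(np.arange(6), X, np.zeros(6), 0.1)


class TestDispersion:
    def test_poisson_data_gives_near_zero_common_dispersion(self):
        lows = []
        for seed in range(3):
            counts, meta, _ = simulate_counts(
                n_features=500, phi=0.0, frac_de=0, seed=seed)
            d = build_designs(meta)
            off = np.log(counts.sum(axis=0).to_numpy(float))
            phi_c, _ = estimate_dispersions(counts, d["cells"], off)
            lows.append(phi_c)
        assert max(lows) <= 0.05

    def test_nb_dispersion_recovered_within_band(self):
        counts, meta, _ = simulate_counts(n_features=500, phi=0.4, frac_de=0, seed=7)
        d = build_designs(meta)
        off = np.log(counts.sum(axis=0).to_numpy(float))
        phi_c, phi_t = estimate_dispersions(counts, d["cells"], off)
        assert 0.3 <= phi_c <= 0.5
        assert 0.2 <= np.median(phi_t) <= 0.6

    def test_single_feature_tagwise_equals_common(self):
        counts, meta, _ = simulate_counts(n_features=1, phi=0.3, frac_de=0, seed=3)
        d = build_designs(meta)
        off = np.log(np.maximum(counts.sum(axis=0).to_numpy(float), 1.0))
        phi_c, phi_t = estimate_dispersions(counts, d["cells"], off)
        assert phi_t[0] == pytest.approx(phi_c, rel=1e-9)


class TestLrt:
    def test_identical_fits_give_zero_statistic(self):
        y = np.array([4, 6, 5, 7], float)
        X = np.ones((4, 1))
        fit = fit_nb_glm(y, X, np.zeros(4), 0.1)
        D, p = lrt_contrast(fit, fit, df=1)
        assert D[0] == 0.0 and p[0] == 1.0

    def test_chi2_critical_value(self):
        assert chi2.sf(3.841, 1) == pytest.approx(0.0500, abs=5e-4)

    def test_non_nested_designs_raise(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(10, 6).astype(float)
        X1 = np.column_stack([np.ones(6), np.arange(6.0)])
        X2 = np.column_stack([np.ones(6), rng.normal(size=6)])
        f1 = fit_nb_glm(y, X1, np.zeros(6), 0.1)
        f2 = fit_nb_glm(y, X2, np.zeros(6), 0.1)
        with pytest.raises(ValueError, match="nested"):
            lrt_contrast(f1, f2, df=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_type_i_error_calibrated_on_null_data(self, seed):
        """Null simulation: raw p < 0.05 in 5% +/- 2% of 1000 features."""
        counts, meta, _ = simulate_counts(
            n_features=1000, phi=0.2, frac_de=0, seed=100 + seed)
        res = run_differential(counts, meta)
        for name in ("RF_vs_FD", "Rplus_vs_Rminus"):
            frac = (res["contrasts"][name]["p"] < 0.05).mean()
            assert 0.03 <= frac <= 0.07


class TestBh:
    def test_hand_computed_step_up(self):
        adj, flags = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_all_ones(self):
        adj, flags = adjust_bh(np.ones(5))
        assert (adj == 1).all() and not flags.any()

    def test_single_p_unchanged(self):
        adj, _ = adjust_bh(np.array([0.031]))
        assert adj[0] == pytest.approx(0.031)

    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        adj, _ = adjust_bh(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))


def brute_force_complete_linkage(X):
    """O(n^3) agglomeration oracle returning sorted merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    np.linalg.norm(X[i] - X[j])
                    for i in clusters[a] for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestLogFcCluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        hm = logfc_cluster(m)
        assert hm.row_linkage[0, 2] == 0.0
        assert set(hm.row_linkage[0, :2].astype(int)) == {0, 1}

    def test_three_collinear_points_by_hand(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0]])
        hm = logfc_cluster(m)
        assert hm.row_linkage[0, 2] == pytest.approx(1.0)
        assert hm.row_linkage[1, 2] == pytest.approx(10.0)

    def test_merge_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 6))
        hm = logfc_cluster(pd.DataFrame(X))
        np.testing.assert_allclose(
            sorted(hm.row_linkage[:, 2]), brute_force_complete_linkage(X),
            rtol=1e-10,
        )

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        hm = logfc_cluster(pd.DataFrame(rng.normal(size=(15, 4))))
        assert (np.diff(hm.row_linkage[:, 2]) >= 0).all()

    def test_non_finite_matrix_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            logfc_cluster(pd.DataFrame([[np.nan, 1.0]]))


@pytest.fixture(scope="module")
def planted():
    out = []
    for seed in range(10):
        counts, meta, truth = simulate_counts(
            n_features=300, phi=0.2, frac_de=0.1, lfc=2.0, seed=200 + seed)
        res = run_differential(counts, meta)
        out.append((res, truth))
    return out


class TestRunDifferential:
    def test_sensitivity_and_fdr_across_seeds(self, planted):
        """Planted |log2FC|=2 at phi=0.2, n=3/group: sensitivity >= 0.8,
        empirical FDR <= 0.10 (mean over 10 seeds)."""
        sens, fdrs = [], []
        for res, truth in planted:
            de = set(truth["de_features"])
            flags = res["flags"][["RF_vs_FD", "Rplus_vs_Rminus"]]
            called = set(flags.index[flags.any(axis=1)])
            tp = len(called & de)
            sens.append(tp / len(de))
            fdrs.append((len(called) - tp) / max(len(called), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdrs) <= 0.10

    def test_zero_interaction_rarely_flagged(self, planted):
        """Additive truth: the interaction LRT flags <= alpha*m after BH."""
        for res, _ in planted:
            m = len(res["interaction"])
            assert res["interaction"]["significant"].sum() <= 0.05 * m

    def test_log2fc_sign_and_magnitude(self, planted):
        """Estimated log2FC tracks the planted effect on well-expressed
        features: signs agree, and the errors are small on average (single
        weak features can deviate by sampling noise at n = 3/group)."""
        errors = []
        for res_, truth_ in planted[:3]:
            lfc_mat = res_["log2fc_matrix"]
            for f in truth_["de_features"]:
                i = list(lfc_mat.index).index(f)
                if truth_["base_mean"][i] < 20:
                    continue
                typ = truth_["de_type"][i]
                planted_lfc = truth_["lfc"][i]
                col = "Rplus_vs_Rminus" if typ == "line" else "RF_vs_FD"
                est = lfc_mat.loc[f, col]
                assert np.sign(est) == np.sign(planted_lfc)
                errors.append(abs(est - planted_lfc))
        assert np.mean(errors) < 0.5
        assert np.quantile(errors, 0.9) < 1.0

    def test_adjusted_p_properties(self, planted):
        res, _ = planted[0]
        for name, df in res["contrasts"].items():
            assert (df["p_adj"] >= df["p"] - 1e-12).all()
            assert df["D"].min() >= -1e-8
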
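"""-dCt transform, consensus intra-animal correlation, and moderated t."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from plasmamir.qpcr import (
    _sample_meta,
    consensus_correlation,
    delta_ct,
    fit_moderated,
    squeeze_var,
    trigamma_inverse,
)
from plasmamir.simulate import simulate_qpcr


@pytest.fixture(scope="module")
def noisy_panel():
    records, truth = simulate_qpcr(n_mirnas=6, sigma_a=0.8, sigma_e=0.4, seed=9)
    ab = delta_ct(records)
    meta = _sample_meta(records)
    return ab, meta, truth


class TestDeltaCt:
    def test_equal_target_and_reference_gives_zero(self):
        rec = pd.DataFrame(
            {"mirna": ["m"], "animal": ["a1"], "line": ["R+"],
             "condition": ["FD"], "batch": ["b1"], "ct": [25.0],
             "reference_ct": [25.0]}
        )
        assert delta_ct(rec).iloc[0, 0] == 0.0

    def test_one_cycle_lower_is_plus_one(self):
        rec = pd.DataFrame(
            {"mirna": ["m"], "animal": ["a1"], "line": ["R+"],
             "condition": ["FD"], "batch": ["b1"], "ct": [24.0],
             "reference_ct": [25.0]}
        )
        assert delta_ct(rec).iloc[0, 0] == 1.0

    def test_technical_replicates_averaged_on_ct_scale(self):
        rec = pd.DataFrame(
            {"mirna": ["m", "m"], "animal": ["a1", "a1"],
             "line": ["R+", "R+"], "condition": ["FD", "FD"],
             "batch": ["b1", "b1"], "ct": [24.0, 26.0],
             "reference_ct": [25.0, 25.0]}
        )
        assert delta_ct(rec).iloc[0, 0] == 0.0

    def test_zero_noise_recovers_planted_ddct_exactly(self):
        records, truth = simulate_qpcr(sigma_a=0.0, sigma_e=0.0, seed=1)
        ab = delta_ct(records)
        meta = _sample_meta(records)
        # -ddCt between conditions == planted condition effect
        for m in ab.index:
            rf = ab.loc[m, meta.index[meta["condition"] == "RF"]].mean()
            fd = ab.loc[m, meta.index[meta["condition"] == "FD"]].mean()
            assert rf - fd == pytest.approx(
                truth["effects"].loc[m, "condition"], abs=1e-12)

    def test_global_mean_reference(self):
        records, _ = simulate_qpcr(seed=2)
        ab = delta_ct(records, reference="global-mean")
        np.testing.assert_allclose(ab.mean(axis=0), 0.0, atol=1e-12)

    def test_nonpositive_ct_rejected(self):
        rec = pd.DataFrame(
            {"mirna": ["m"], "animal": ["a"], "line": ["R+"],
             "condition": ["FD"], "ct": [-1.0], "reference_ct": [20.0]})
        with pytest.raises(ValueError):
            delta_ct(rec)


class TestConsensusCorrelation:
    def test_duplicated_measurements_drive_rho_to_cap(self):
        records, _ = simulate_qpcr(n_mirnas=8, sigma_a=1.0, sigma_e=1e-8, seed=3)
        ab = delta_ct(records)
        rho = consensus_correlation(ab, _sample_meta(records))
        assert rho > 0.95

    def test_independent_measurements_near_zero(self):
        """|rho| small under sigma_a = 0 (20 miRNAs x 15 animals)."""
        rhos = []
        for seed in range(10):
            records, _ = simulate_qpcr(n_mirnas=20, sigma_a=0.0, sigma_e=0.5,
                                       seed=50 + seed)
            rhos.append(consensus_correlation(delta_ct(records),
                                              _sample_meta(records)))
        assert np.abs(rhos).max() <= 0.15

    def test_planted_icc_recovered(self):
        """Mean estimate over 10 seeds within +/-0.15 of planted ICC 0.5."""
        rhos = []
        for seed in range(10):
            records, truth = simulate_qpcr(
                n_mirnas=20, sigma_a=0.5, sigma_e=0.5, seed=seed)
            assert truth["icc"] == pytest.approx(0.5)
            rhos.append(consensus_correlation(delta_ct(records),
                                              _sample_meta(records)))
        assert abs(np.mean(rhos) - 0.5) <= 0.15

    def test_no_repeated_blocks_returns_zero_with_warning(self):
        records, _ = simulate_qpcr(seed=4)
        records = records[records["condition"] == "FD"]  # one obs per animal
        with pytest.warns(UserWarning, match="repeated"):
            rho = consensus_correlation(delta_ct(records), _sample_meta(records))
        assert rho == 0.0


class TestSqueezeVar:
    def test_matches_limma_reference_implementation(self, tmp_path):
        """Independent oracle: limma::squeezeVar on the same variances."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; the limma oracle cannot run")
        rng = np.random.default_rng(42)
        d = 12
        true_var = 0.05 * 8.0 / rng.chisquare(8.0, size=40)
        s2 = true_var * rng.chisquare(d, size=40) / d
        d0, s02, post = squeeze_var(s2, d)
        path = tmp_path / "s2.txt"
        np.savetxt(path, s2)
        script = (
            'suppressMessages(library(limma));'
            f's2 <- scan("{path}", quiet=TRUE);'
            f'sq <- squeezeVar(s2, df={d});'
            'cat(sprintf("%.12g", c(sq$df.prior, sq$var.prior, sq$var.post)), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vals = np.array([float(v) for v in out.stdout.split()])
        assert d0 == pytest.approx(vals[0], rel=1e-6)
        assert s02 == pytest.approx(vals[1], rel=1e-6)
        np.testing.assert_allclose(post, vals[2:], rtol=1e-6)

    def test_posterior_between_extremes(self):
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(10, 30) / 10
        d0, s02, post = squeeze_var(s2, 10)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.1, 1.0, 7.5, 60.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)


class TestModerated:
    def test_d0_zero_equals_ordinary_gls_t(self, noisy_panel):
        ab, meta, _ = noisy_panel
        rho = consensus_correlation(ab, meta)
        f0 = fit_moderated(ab, meta, rho=rho, d0_override=0.0)
        # ordinary t from the unshrunk variances
        t_ord = f0.coefficients["line[R+]"] / f0.stderr["line[R+]"]
        np.testing.assert_allclose(f0.tests["line"]["t"], t_ord, rtol=1e-10)

    def test_moderation_shrinks_toward_pooled_statistic(self, noisy_panel):
        ab, meta, _ = noisy_panel
        rho = consensus_correlation(ab, meta)
        f0 = fit_moderated(ab, meta, rho=rho, d0_override=0.0)
        fm = fit_moderated(ab, meta, rho=rho)
        fp = fit_moderated(ab, meta, rho=rho, d0_override=1e9)  # full pooling
        for m in ab.index:
            t0 = f0.tests["line"].loc[m, "t"]
            tm = fm.tests["line"].loc[m, "t"]
            tp = fp.tests["line"].loc[m, "t"]
            lo, hi = sorted([t0, tp])
            assert lo - 1e-9 <= tm <= hi + 1e-9

    def test_near_constant_response_gives_t_near_zero(self):
        records, _ = simulate_qpcr(line_effect=0.0, condition_effect=0.0,
                                   batch_effect=0.0, sigma_a=0.0,
                                   sigma_e=1e-6, seed=5)
        ab = delta_ct(records)
        fit = fit_moderated(ab, _sample_meta(records), rho=0.0)
        # t is scale-free, so residual numerical noise keeps it O(1);
        # the effect estimates themselves must be at the noise floor
        assert np.abs(fit.tests["line"]["coef"]).max() < 1e-4
        assert (fit.tests["line"]["p"] > 0.05).all()

    def test_single_level_batch_dropped(self):
        records, _ = simulate_qpcr(seed=6)
        records["batch"] = "b1"
        fit = fit_moderated(delta_ct(records), _sample_meta(records), rho=0.0)
        assert not any(c.startswith("batch") for c in fit.coefficients.columns)

    def test_results_invariant_to_mirna_order(self, noisy_panel):
        ab, meta, _ = noisy_panel
        f1 = fit_moderated(ab, meta, rho=0.3)
        f2 = fit_moderated(ab.iloc[::-1], meta, rho=0.3)
        t1 = f1.tests["line"]["t"].sort_index()
        t2 = f2.tests["line"]["t"].sort_index()
        np.testing.assert_allclose(t1, t2, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_line_effects_detected(self, seed):
        """Panel of 6 miRNAs, 15 animals, 2 conditions: planted line
        effects called at FDR 5% in most seeds (checked per seed here with
        a clear 2-cycle effect)."""
        effects = pd.DataFrame(
            {"line": [2.0, 2.0, 2.0, 0.0, 0.0, 0.0],
             "condition": [1.0] * 6},
            index=[f"qmir{m}" for m in range(6)])
        records, _ = simulate_qpcr(
            n_mirnas=6, effects_per_mirna=effects, sigma_a=0.5, sigma_e=0.4,
            seed=800 + seed)
        ab = delta_ct(records)
        meta = _sample_meta(records)
        fit = fit_moderated(ab, meta)
        called = set(fit.tests["line"].index[fit.tests["line"]["significant"]])
        assert {"qmir0", "qmir1", "qmir2"} <= called
        assert not ({"qmir3", "qmir4", "qmir5"} & called) or len(called) <= 4
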
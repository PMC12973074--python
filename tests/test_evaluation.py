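import numpy as np
import pytest
from scipy import stats

from eeg2bold.datatypes import TaskEvent
from eeg2bold.evaluation import (
    FoldResult,
    downsample_check,
    event_regressor,
    functional_validity,
    group_tests,
    pearson_r,
    permutation_pvalue,
    phase_randomize,
    specificity_report,
)


class TestPearson:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ])
    def test_reference_values(self, a, b, expected):
        assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert pearson_r([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2, 3])


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved(self, rng):
        y = rng.standard_normal(501)
        surr = phase_randomize(y, seed=0)
        np.testing.assert_allclose(np.abs(np.fft.rfft(surr)),
                                   np.abs(np.fft.rfft(y)), rtol=1e-9)
        y_even = rng.standard_normal(500)
        surr_even = phase_randomize(y_even, seed=0)
        np.testing.assert_allclose(np.abs(np.fft.rfft(surr_even)),
                                   np.abs(np.fft.rfft(y_even)), rtol=1e-9)

    def test_constant_input_unchanged(self):
        y = np.full(16, 3.5)
        np.testing.assert_allclose(phase_randomize(y, 1), y, atol=1e-12)

    def test_pure_sinusoid_keeps_frequency_and_amplitude(self):
        t = np.arange(256)
        y = 2.0 * np.sin(2 * np.pi * 8 * t / 256)
        surr = phase_randomize(y, seed=4)
        spec = np.abs(np.fft.rfft(surr))
        assert np.argmax(spec) == 8
        assert surr.std() == pytest.approx(y.std(), rel=1e-9)
        assert not np.allclose(surr, y)

    def test_output_is_real_and_seeded(self, rng):
        y = rng.standard_normal(100)
        s1, s2 = phase_randomize(y, 7), phase_randomize(y, 7)
        np.testing.assert_array_equal(s1, s2)
        assert not np.allclose(phase_randomize(y, 8), s1)


class TestPermutationPvalue:
    def test_add_one_floor(self, rng):
        """A perfect correlate beats all surrogates: p = 1/1001."""
        y = np.cumsum(rng.standard_normal(300))
        p, null = permutation_pvalue(y, y, n_surrogates=1000, seed=0)
        assert p == pytest.approx(1 / 1001)
        assert null.size == 1000

    def test_null_uniformity(self, rng):
        """Under independence the p-value distribution is uniform (KS test)."""
        ps = []
        for i in range(500):
            a = rng.standard_normal(64)
            b = rng.standard_normal(64)
            p, _ = permutation_pvalue(a, b, n_surrogates=99, seed=i)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_rejection_rate_calibrated(self, rng):
        ps = []
        for i in range(500):
            a = rng.standard_normal(80)
            b = rng.standard_normal(80)
            p, _ = permutation_pvalue(a, b, n_surrogates=99, seed=1000 + i)
            ps.append(p)
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert rate == pytest.approx(0.05, abs=0.02)


class TestDownsample:
    def test_identical_signals_give_unity(self, rng):
        native = rng.standard_normal(50)
        t_native = np.arange(50) * 2.0
        t_fine = np.arange(0, 99.0, 0.01)
        fine = np.interp(t_fine, t_native, native)
        # binned means track the native series imperfectly; use the exact
        # construction instead: repeat each native sample over its TR bin
        fine = np.repeat(native, 200)
        r = downsample_check(fine, native, fs_pred_hz=100.0, tr_s=2.0)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_duration_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample_check(rng.standard_normal(1000), rng.standard_normal(50))


class TestEventRegressor:
    def test_no_events_gives_zero(self):
        np.testing.assert_array_equal(event_regressor([], "win", 100.0, 500), 0.0)

    def test_single_event_peaks_at_hrf_latency(self):
        ev = TaskEvent("run1", 0, 2.0, 2.0, "win")
        reg = event_regressor([ev], "win", 100.0, 2000)
        assert np.argmax(reg) / 100.0 == pytest.approx(2.0 + 5.0, abs=0.02)

    def test_balanced_runs_have_equal_mass(self):
        events = [TaskEvent("r", i, 5.0 + 10 * i, 2.0, "win" if i % 2 else "loss")
                  for i in range(10)]
        win = event_regressor(events, "win", 10.0, 2000)
        loss = event_regressor(events, "loss", 10.0, 2000)
        # identical kernel and equal event counts; small tail differences only
        assert win.sum() == pytest.approx(loss.sum(), rel=0.01)

    def test_out_of_range_onset_rejected(self):
        ev = TaskEvent("r", 0, 99.0, 2.0, "win")
        with pytest.raises(ValueError):
            event_regressor([ev], "win", 100.0, 500)


class TestFunctionalValidity:
    def _events(self):
        return [TaskEvent("r", i, 5.0 + 10 * i, 2.0,
                          "win" if i % 2 == 0 else "loss") for i in range(20)]

    def test_recovers_planted_betas(self, rng):
        events = self._events()
        fs, n = 10.0, 2100
        win = event_regressor(events, "win", fs, n)
        loss = event_regressor(events, "loss", fs, n)
        y = 2.0 * win + 1.0 * loss + 0.1 * rng.standard_normal(n)
        bw, bl = functional_validity(y, events, fs)
        assert bw == pytest.approx(2.0, abs=0.1)
        assert bl == pytest.approx(1.0, abs=0.1)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS agrees with the closed-form (X'X)^-1 X'y solution."""
        events = self._events()
        fs, n = 10.0, 2100
        y = rng.standard_normal(n)
        bw, bl = functional_validity(y, events, fs)
        X = np.column_stack([
            np.ones(n),
            event_regressor(events, "win", fs, n),
            event_regressor(events, "loss", fs, n),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert bw == pytest.approx(beta[1], abs=1e-9)
        assert bl == pytest.approx(beta[2], abs=1e-9)

    def test_independent_noise_gives_null_betas(self, rng):
        events = self._events()
        sig = 0
        for i in range(20):
            y = rng.standard_normal(2100)
            bw, bl = functional_validity(y, events, 10.0)
            assert abs(bw) < 1.0 and abs(bl) < 1.0
        # direction is arbitrary under the null
        # (tested at the group level in test_workbench)


class TestSpecificity:
    def test_beta_sign_matches_r_without_nuisance(self, rng):
        y = rng.standard_normal(500)
        rois = {"A": y + rng.standard_normal(500),
                "B": -y + rng.standard_normal(500)}
        rep = specificity_report(y, rois)
        for label in rois:
            r, beta = rep[label]
            assert np.sign(r) == np.sign(beta)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            specificity_report(rng.standard_normal(100),
                               {"A": rng.standard_normal(90)})


class TestGroupTests:
    def _fold(self, fid, r, model="dl", roi_r=None, bw=0.0, bl=0.0):
        y = np.zeros(4)
        return FoldResult(fold_id=fid, y_true=y, y_pred=y, fs_hz=1.0, r=r,
                          permutation_p=0.01, roi_r=roi_r or {}, beta_win=bw,
                          beta_loss=bl, r_downsampled=r, model=model)

    def test_identical_inputs_flagged_degenerate(self):
        dl = [self._fold(i, 0.3) for i in range(5)]
        lin = [self._fold(i, 0.3, "linear") for i in range(5)]
        rep = group_tests(dl, lin)
        assert rep.paired_tests["dl_vs_linear_r"]["degenerate"] == 1.0
        assert rep.paired_tests["dl_vs_linear_r"]["t"] == 0.0

    def test_df_is_folds_minus_one(self):
        dl = [self._fold(i, 0.3 + 0.01 * i) for i in range(20)]
        lin = [self._fold(i, 0.2 + 0.01 * i, "linear") for i in range(20)]
        rep = group_tests(dl, lin)
        assert rep.paired_tests["dl_vs_linear_r"]["df"] == 19

    def test_matches_textbook_paired_t(self):
        """Five-fold hand check against the closed-form paired-t formula."""
        a = np.array([0.5, 0.4, 0.45, 0.6, 0.35])
        b = np.array([0.3, 0.35, 0.4, 0.45, 0.3])
        dl = [self._fold(i, a[i]) for i in range(5)]
        lin = [self._fold(i, b[i], "linear") for i in range(5)]
        rep = group_tests(dl, lin)
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert rep.paired_tests["dl_vs_linear_r"]["t"] == pytest.approx(
            t_expected, abs=1e-9
        )

    def test_summary_recomputable_from_table(self):
        dl = [self._fold(i, 0.1 * i) for i in range(6)]
        rep = group_tests(dl, None)
        table_r = rep.per_fold.loc[rep.per_fold.model == "dl", "r"].to_numpy()
        assert rep.summary["dl_r"]["mean"] == pytest.approx(table_r.mean())
        assert rep.summary["dl_r"]["sd"] == pytest.approx(table_r.std(ddof=1))

    def test_mismatched_folds_rejected(self):
        dl = [self._fold(i, 0.3) for i in range(4)]
        lin = [self._fold(i + 1, 0.2, "linear") for i in range(4)]
        with pytest.raises(ValueError):
            group_tests(dl, lin)
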
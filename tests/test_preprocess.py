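import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eeg2bold.datatypes import EegRecording, RoiBoldSeries
from eeg2bold.preprocess import (
    align_pair,
    bandpass,
    common_average_reference,
    extract_windows,
    zscore,
)


class TestZscore:
    def test_definition(self):
        z = zscore(np.array([1.0, 2.0, 3.0]))
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_constant_channel_maps_to_zero(self):
        np.testing.assert_array_equal(zscore(np.array([5.0, 5.0, 5.0])), 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40))
    def test_idempotent(self, values):
        x = np.asarray(values)
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.array([1.0]))

    def test_per_channel_axis(self, rng):
        x = rng.standard_normal((4, 100)) * [[1], [2], [3], [4]]
        z = zscore(x)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1, atol=1e-9)


class TestCommonAverageReference:
    def test_column_means_zero(self, random_eeg):
        out = common_average_reference(random_eeg)
        np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-9)

    def test_idempotent(self, random_eeg):
        once = common_average_reference(random_eeg)
        twice = common_average_reference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        rec = EegRecording(np.zeros((1, 10)) + 1.0, ["e1"], 100.0, "r")
        with pytest.raises(ValueError):
            common_average_reference(rec)


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs = 100.0
        t = np.arange(3000) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        rec = EegRecording(tone[None, :], ["e1"], fs, "r")
        out = bandpass(rec, 0.5, 45.0)
        mid = slice(500, 2500)  # avoid filter edges
        ratio = out.data[0, mid].std() / tone[mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_slow_drift_attenuated(self):
        fs = 100.0
        t = np.arange(60000) / fs
        drift = np.sin(2 * np.pi * 0.05 * t)
        rec = EegRecording(drift[None, :], ["e1"], fs, "r")
        out = bandpass(rec, 0.5, 45.0)
        atten_db = 20 * np.log10(drift.std() / out.data[0].std())
        assert atten_db >= 20

    def test_band_outside_nyquist_rejected(self, random_eeg):
        with pytest.raises(ValueError):
            bandpass(random_eeg, 0.5, 60.0)


class TestAlignPair:
    def _pair_inputs(self, rng, n_s=120, fs_eeg=100.0, tr=2.0):
        eeg = EegRecording(rng.standard_normal((3, int(n_s * fs_eeg))),
                           ["e1", "e2", "e3"], fs_eeg, "run1")
        bold = RoiBoldSeries(rng.standard_normal(int(n_s / tr)), 1 / tr, "VS",
                             "target", "run1")
        return eeg, bold

    def test_common_rate_and_shift_trim(self, rng):
        eeg, bold = self._pair_inputs(rng)
        pair = align_pair(eeg, bold, fs_common=100.0, delay_s=6.0)
        assert pair.fs_hz == 100.0
        assert pair.eeg.n_samples == pair.bold.n_samples
        # bold covers (n_vol-1)*tr => 11801 samples at 100 Hz, minus 600 shift
        assert pair.n_samples == 11801 - 600

    def test_zero_delay_is_identity_alignment(self, rng):
        eeg, bold = self._pair_inputs(rng)
        pair = align_pair(eeg, bold, fs_common=100.0, delay_s=0.0)
        np.testing.assert_array_equal(pair.eeg.data[:, :100], eeg.data[:, :100])
        assert pair.n_samples == min(eeg.n_samples, 11801)

    def test_delay_longer_than_recording_rejected(self, rng):
        eeg, bold = self._pair_inputs(rng, n_s=8)
        with pytest.raises(ValueError):
            align_pair(eeg, bold, delay_s=10.0)

    def test_downsampling_preserves_tone_amplitude(self):
        """1 kHz -> 100 Hz decimation keeps a 10 Hz tone within 5%."""
        fs = 1000.0
        t = np.arange(int(fs * 30)) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        eeg = EegRecording(tone[None, :], ["e1"], fs, "run1")
        bold = RoiBoldSeries(np.random.default_rng(0).standard_normal(15),
                             0.5, "VS", "target", "run1")
        pair = align_pair(eeg, bold, fs_common=100.0, delay_s=0.0)
        mid = slice(200, pair.n_samples - 200)
        assert pair.eeg.data[0, mid].std() == pytest.approx(tone.std(), rel=0.05)

    def test_planted_delay_removed(self, desk_session):
        """After alignment only the HRF's own peak lag remains."""
        from eeg2bold.hrf import canonical_hrf
        session = desk_session
        pair = session.pairs["run1"]
        env = session.truth.envelopes["run1"][0] ** 2
        env = (env - env.mean()) / env.std()
        kernel = canonical_hrf(100.0)
        conv = np.convolve(env, kernel)[: env.size][: pair.n_samples]
        from scipy.signal import correlate
        b = pair.bold.values - pair.bold.values.mean()
        c = conv - conv.mean()
        cc = correlate(b, c)
        lag = (np.argmax(cc) - (pair.n_samples - 1)) / pair.fs_hz
        assert abs(lag) <= 1.0  # transport delay gone; conv already carries HRF lag


class TestExtractWindows:
    def test_full_scale_window_shape(self, rng):
        eeg = EegRecording(rng.standard_normal((62, 20000)),
                           [f"e{i+1}" for i in range(62)], 100.0, "run1")
        bold = RoiBoldSeries(rng.standard_normal(20000), 100.0, "VS", "target", "run1")
        from eeg2bold.preprocess import AlignedPair
        pair = AlignedPair(eeg, bold, 100.0, 6.0)
        wins = extract_windows(pair, 160.0, 5, seed=0)
        assert all(w.X.shape == (62, 16000) for w in wins)
        assert all(w.y.size == 16000 for w in wins)

    def test_starts_in_bounds_and_seeded(self, rng):
        eeg = EegRecording(rng.standard_normal((3, 5000)), ["e1", "e2", "e3"],
                           100.0, "run1")
        bold = RoiBoldSeries(rng.standard_normal(5000), 100.0, "VS", "target", "run1")
        from eeg2bold.preprocess import AlignedPair
        pair = AlignedPair(eeg, bold, 100.0, 6.0)
        wins = extract_windows(pair, 10.0, 50, seed=3)
        assert all(0 <= w.start_index <= 5000 - 1000 for w in wins)
        again = extract_windows(pair, 10.0, 50, seed=3)
        assert [w.start_index for w in wins] == [w.start_index for w in again]
        assert not any(np.isnan(w.X).any() for w in wins)

    def test_window_longer_than_run_rejected(self, rng):
        eeg = EegRecording(rng.standard_normal((2, 500)), ["e1", "e2"], 100.0, "r")
        bold = RoiBoldSeries(rng.standard_normal(500), 100.0, "VS", "target", "r")
        from eeg2bold.preprocess import AlignedPair
        pair = AlignedPair(eeg, bold, 100.0, 0.0)
        with pytest.raises(ValueError):
            extract_windows(pair, 10.0, 1, seed=0)
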
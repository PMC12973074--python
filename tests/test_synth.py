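import dataclasses

import numpy as np
import pytest
from scipy import signal

from eeg2bold.synth import (
    CONTROL_ROIS,
    SourceSpec,
    SyntheticConfig,
    load_session,
    make_task_events,
    oracle_envelope_r,
    simulate_session,
    smooth_pattern,
    write_session,
)


class TestTaskEvents:
    def test_full_scale_counts(self):
        """4 runs x 100 trials with exactly 50/50 win-loss balance per run."""
        cfg = SyntheticConfig(seed=1)
        events = make_task_events(cfg)
        assert len(events) == 400
        for run in cfg.run_ids():
            run_events = [e for e in events if e.run_id == run]
            assert len(run_events) == 100
            wins = sum(e.outcome == "win" for e in run_events)
            assert wins == 50

    def test_onsets_increasing_and_in_bounds(self):
        cfg = SyntheticConfig(seed=2)
        events = make_task_events(cfg)
        for run in cfg.run_ids():
            onsets = [e.onset_s for e in events if e.run_id == run]
            assert all(b > a for a, b in zip(onsets, onsets[1:]))
            assert onsets[-1] + 2.0 <= cfg.run_duration_s

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=5)
        assert make_task_events(cfg) == make_task_events(cfg)
        other = dataclasses.replace(cfg, seed=6)
        assert make_task_events(cfg) != make_task_events(other)

    def test_odd_trial_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SyntheticConfig(trials_per_run=99)


class TestSimulateSession:
    def test_default_bold_length(self):
        """Each run yields 530 volumes at TR = 2 s."""
        runs, bolds, events, truth = simulate_session(SyntheticConfig(seed=0))
        assert all(b.n_samples == 530 for b in bolds["VS"])
        assert all(b.fs_hz == 0.5 for b in bolds["VS"])
        assert len(runs) == 4 and runs[0].n_channels == 62

    def test_outputs_finite_and_labelled(self, tiny_cfg, tiny_session):
        runs, bolds, events, truth = tiny_session
        for rec in runs:
            assert np.all(np.isfinite(rec.data))
            assert rec.channel_labels == [f"e{i+1}" for i in range(tiny_cfg.n_channels)]
        assert set(bolds) == {"VS", *CONTROL_ROIS}

    def test_seeded_determinism(self, tiny_cfg, tiny_session):
        runs2, bolds2, _, _ = simulate_session(tiny_cfg)
        np.testing.assert_array_equal(tiny_session[0][0].data, runs2[0].data)
        np.testing.assert_array_equal(tiny_session[1]["VS"][2].values,
                                      bolds2["VS"][2].values)

    def test_source_spectrum_peaks_in_band(self, tiny_cfg):
        """Periodogram argmax of the planted source falls inside its band."""
        cfg = dataclasses.replace(tiny_cfg, eeg_noise=dataclasses.replace(
            tiny_cfg.eeg_noise, pink_sd=0.0, white_sd=0.0))
        runs, *_ = simulate_session(cfg)
        src = cfg.sources[0]
        best = int(np.argmax(np.abs(src.spatial_pattern)))
        f, psd = signal.welch(runs[0].data[best], fs=cfg.fs_hz, nperseg=1024)
        peak = f[np.argmax(psd)]
        assert abs(peak - src.center_freq_hz) <= src.bandwidth_hz

    def test_uncoupled_controls_are_independent(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, control_coupling=0.0,
                                  volumes_per_run=530, trials_per_run=6)
        _, bolds, _, _ = simulate_session(cfg)
        r = np.corrcoef(bolds["VS"][0].values, bolds["VC"][0].values)[0, 1]
        assert abs(r) < 0.1

    def test_source_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SyntheticConfig(
                n_channels=8,
                sources=[SourceSpec(spatial_pattern=smooth_pattern(8),
                                    center_freq_hz=60.0)],
            )

    def test_delay_places_bold_peak_after_envelope(self, tiny_cfg, tiny_session):
        """Envelope-to-BOLD lag = transport delay + HRF peak, within 1 TR."""
        _, _, _, truth = tiny_session
        cfg = tiny_cfg
        step = round(cfg.tr_s * cfg.fs_hz)
        env = truth.envelopes["run1"][0] ** 2
        env = (env - env.mean()) / env.std()
        env_v = env[::step][: cfg.volumes_per_run]
        drive = truth.drive["run1"]
        cc = signal.correlate(drive - drive.mean(), env_v - env_v.mean())
        lag_s = (np.argmax(cc) - (env_v.size - 1)) * cfg.tr_s
        assert abs(lag_s - (cfg.hrf_delay_s + 5.0)) <= cfg.tr_s


class TestOracle:
    def test_noiseless_oracle_is_one(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, bold_noise_sd=0.0)
        _, bolds, _, truth = simulate_session(cfg)
        assert oracle_envelope_r(truth, bolds["VS"][0]) == pytest.approx(1.0, abs=1e-6)

    def test_equal_variance_noise_gives_inverse_sqrt2(self):
        """bold_noise_sd equal to the unit drive SD puts r near 1/sqrt(2)."""
        rs = []
        for seed in range(50):
            cfg = SyntheticConfig(
                n_channels=8, n_runs=1, trials_per_run=6, volumes_per_run=300,
                sources=[SourceSpec(spatial_pattern=smooth_pattern(8))],
                bold_noise_sd=1.0, seed=seed,
            )
            _, bolds, _, truth = simulate_session(cfg)
            rs.append(oracle_envelope_r(truth, bolds["VS"][0]))
        assert np.mean(rs) == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_more_noise_means_lower_ceiling(self):
        means = []
        for sd in (1.0, 2.0):
            rs = []
            for seed in range(20):
                cfg = SyntheticConfig(
                    n_channels=8, n_runs=1, trials_per_run=6, volumes_per_run=200,
                    sources=[SourceSpec(spatial_pattern=smooth_pattern(8))],
                    bold_noise_sd=sd, seed=seed,
                )
                _, bolds, _, truth = simulate_session(cfg)
                rs.append(oracle_envelope_r(truth, bolds["VS"][0]))
            means.append(np.mean(rs))
        assert means[1] < means[0]


def test_session_round_trip(tmp_path, tiny_cfg, tiny_session):
    runs, bolds, events, truth = tiny_session
    write_session(tmp_path, runs, bolds, events, truth)
    assert (tmp_path / "events.tsv").exists() and (tmp_path / "truth.json").exists()
    runs2, bolds2, events2 = load_session(tmp_path)
    np.testing.assert_allclose(runs2[1].data, runs[1].data)
    np.testing.assert_allclose(bolds2["PMC"][0].values, bolds["PMC"][0].values)
    assert [e.outcome for e in events2] == [e.outcome for e in events]
    assert [e.trial_index for e in events2] == [e.trial_index for e in events]
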
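"""Synthetic simultaneous EEG-fMRI sessions with known spatio-spectral coupling.

The generator emulates the acquisition geometry of a gambling-task
EEG-fMRI session: 62-channel EEG at a common 100 Hz rate, 4 runs of 100
trials with exactly balanced win/loss feedback, and 530 BOLD volumes per
run at TR = 2 s.  A planted band-limited EEG source drives the target-ROI
("VS") BOLD through an HRF-convolved, transport-delayed power envelope,
with a mild nonlinearity (envelope squared by default) so that a nonlinear
decoder has measurable headroom over a linear one.  Three control ROIs
("VC", "PMC", "STN") receive only a weak share of the same drive, which
makes regional specificity testable.

Everything is seeded through :class:`numpy.random.SeedSequence` so a config
plus seed reproduces a session bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import EegRecording, RoiBoldSeries, TaskEvent
from .hrf import canonical_hrf

__all__ = [
    "SourceSpec",
    "SyntheticConfig",
    "SessionTruth",
    "smooth_pattern",
    "make_task_events",
    "simulate_session",
    "oracle_envelope_r",
    "write_session",
    "load_session",
]

CONTROL_ROIS = ("VC", "PMC", "STN")
TARGET_ROI = "VS"

# Feedback appears 5 s into each trial: 2 s fixation + 1 s choice + 2 s
# highlight delay; it stays on screen for 2 s.
FEEDBACK_OFFSET_S = 5.0
FEEDBACK_DURATION_S = 2.0

# seed-stream tags (mixed with the config seed and run index)
_TAG_EVENTS, _TAG_SOURCE, _TAG_EEG_NOISE, _TAG_BOLD_NOISE, _TAG_CONTROL = range(5)


def smooth_pattern(n_channels: int, center_frac: float = 0.7, width_frac: float = 0.12) -> np.ndarray:
    """Unit-norm Gaussian bump over the channel index.

    A deterministic stand-in for a dipolar scalp topography: channels are
    treated as a 1-D array and the pattern peaks at ``center_frac`` of the
    montage with width ``width_frac``.
    """
    idx = np.arange(n_channels)
    center = center_frac * (n_channels - 1)
    width = max(width_frac * n_channels, 1.0)
    p = np.exp(-0.5 * ((idx - center) / width) ** 2)
    return p / np.linalg.norm(p)


@dataclass
class SourceSpec:
    """One planted spatio-spectral EEG source.

    The source is a band-limited oscillation whose instantaneous amplitude
    is ``baseline_amp``, multiplied by ``win_gain`` or ``loss_gain`` for
    2 s after each feedback onset.  ``coupling_exponent`` shapes the
    envelope-to-BOLD transfer (2 = squared envelope, i.e. band power).
    """

    spatial_pattern: np.ndarray
    center_freq_hz: float = 10.0
    bandwidth_hz: float = 4.0
    baseline_amp: float = 1.0
    win_gain: float = 2.0
    loss_gain: float = 1.2
    coupling_exponent: float = 2.0

    def __post_init__(self) -> None:
        self.spatial_pattern = np.asarray(self.spatial_pattern, dtype=float).ravel()
        norm = np.linalg.norm(self.spatial_pattern)
        if norm == 0:
            raise ValueError("spatial_pattern must be nonzero")
        self.spatial_pattern = self.spatial_pattern / norm
        if self.center_freq_hz <= 0:
            raise ValueError("center_freq_hz must be positive")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")
        if self.win_gain < 0 or self.loss_gain < 0:
            raise ValueError("gains must be >= 0")


@dataclass
class EegNoiseSpec:
    """EEG background: 1/f (power slope 1) plus white sensor noise."""

    pink_sd: float = 1.0
    white_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.pink_sd < 0 or self.white_sd < 0:
            raise ValueError("noise levels must be >= 0")


def _default_sources() -> list[SourceSpec]:
    # amplitude 3x the unit background: the planted source is strong in its
    # band, so envelope estimability on the EEG side is not the binding
    # noise source -- the BOLD-side ceiling (bold_noise_sd) is
    return [SourceSpec(spatial_pattern=smooth_pattern(62), baseline_amp=3.0)]


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic session.

    Defaults mirror the acquisition this generator emulates: 62 channels at
    100 Hz, 4 runs of 100 trials (10 s each, feedback at +5 s), 530 volumes
    per run at TR = 2 s, and a 6 s hemodynamic transport delay.
    ``bold_noise_sd`` = 1 against a unit-variance drive puts the noise
    ceiling (oracle r) near 1/sqrt(2) ~ 0.71.
    """

    n_channels: int = 62
    fs_hz: float = 100.0
    n_runs: int = 4
    trials_per_run: int = 100
    trial_duration_s: float = 10.0
    tr_s: float = 2.0
    volumes_per_run: int = 530
    hrf_delay_s: float = 6.0
    sources: list[SourceSpec] = field(default_factory=_default_sources)
    eeg_noise: EegNoiseSpec = field(default_factory=EegNoiseSpec)
    bold_noise_sd: float = 1.0
    control_coupling: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_run % 2 != 0:
            raise ValueError("trials_per_run must be even for exact win/loss balance")
        if self.volumes_per_run * self.tr_s < self.trials_per_run * self.trial_duration_s:
            raise ValueError("run too short for the requested trials")
        if self.bold_noise_sd < 0:
            raise ValueError("bold_noise_sd must be >= 0")
        if not 0 <= self.control_coupling < 1:
            raise ValueError("control_coupling must be in [0, 1)")
        nyq = self.fs_hz / 2
        for src in self.sources:
            if src.center_freq_hz >= nyq:
                raise ValueError(
                    f"source frequency {src.center_freq_hz} Hz >= Nyquist {nyq} Hz"
                )
            if src.spatial_pattern.size != self.n_channels:
                raise ValueError("spatial_pattern length must equal n_channels")

    @property
    def run_duration_s(self) -> float:
        return self.volumes_per_run * self.tr_s

    @property
    def samples_per_run(self) -> int:
        return round(self.run_duration_s * self.fs_hz)

    def run_ids(self) -> list[str]:
        return [f"run{k + 1}" for k in range(self.n_runs)]


@dataclass
class SessionTruth:
    """Ground-truth record of one simulated session.

    ``envelopes[run_id]`` holds the (n_sources, n_samples) instantaneous
    amplitude of each source at the EEG rate; ``drive[run_id]`` the
    noiseless z-scored target BOLD at the volume rate.
    """

    config: SyntheticConfig
    envelopes: dict[str, np.ndarray]
    drive: dict[str, np.ndarray]
    patterns: np.ndarray
    center_freqs_hz: np.ndarray
    win_gains: np.ndarray
    loss_gains: np.ndarray
    seed: int


def _rng(seed: int, tag: int, run: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag, run]))


def make_task_events(cfg: SyntheticConfig) -> list[TaskEvent]:
    """Build the balanced feedback-event table for all runs.

    Trials are laid down at fixed ``trial_duration_s`` spacing; feedback
    onset is 5 s into each trial.  Outcome labels are a seeded permutation
    of exactly 50% win / 50% loss per run.
    """
    events: list[TaskEvent] = []
    half = cfg.trials_per_run // 2
    for k, run_id in enumerate(cfg.run_ids()):
        rng = _rng(cfg.seed, _TAG_EVENTS, k)
        outcomes = np.array(["win"] * half + ["loss"] * half)
        rng.shuffle(outcomes)
        magnitudes = rng.choice([5, 25], size=cfg.trials_per_run)
        for i in range(cfg.trials_per_run):
            onset = i * cfg.trial_duration_s + FEEDBACK_OFFSET_S
            events.append(
                TaskEvent(
                    run_id=run_id,
                    trial_index=i,
                    onset_s=onset,
                    duration_s=FEEDBACK_DURATION_S,
                    outcome=str(outcomes[i]),
                    magnitude=int(magnitudes[i]),
                )
            )
    return events


def _band_oscillation(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """White noise band-passed to [lo, hi], unit variance."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """1/f-power background, unit variance per channel."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((shape[0], freqs.size))
            + 1j * rng.standard_normal((shape[0], freqs.size))) * scale
    x = np.fft.irfft(spec, n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _gain_profile(cfg: SyntheticConfig, events: list[TaskEvent], run_id: str,
                  src: SourceSpec) -> np.ndarray:
    """Multiplicative amplitude modulation over one run at the EEG rate."""
    gain = np.ones(cfg.samples_per_run)
    for ev in events:
        if ev.run_id != run_id:
            continue
        a = round(ev.onset_s * cfg.fs_hz)
        b = round((ev.onset_s + FEEDBACK_DURATION_S) * cfg.fs_hz)
        gain[a:b] = src.win_gain if ev.outcome == "win" else src.loss_gain
    return gain


def _drive_to_bold(cfg: SyntheticConfig, envelope: np.ndarray, exponent: float) -> np.ndarray:
    """Noiseless z-scored target BOLD at the volume rate from one envelope.

    The envelope is raised to the coupling exponent, z-scored, convolved
    with the canonical HRF, shifted by the transport delay (BOLD at t
    reflects the envelope at t - hrf_delay_s) and sampled every TR.
    """
    drive = envelope ** exponent
    drive = (drive - drive.mean()) / drive.std()
    kernel = canonical_hrf(cfg.fs_hz)
    conv = np.convolve(drive, kernel)[: drive.size]
    shift = round(cfg.hrf_delay_s * cfg.fs_hz)
    delayed = np.concatenate([np.zeros(shift), conv[: drive.size - shift]])
    step = round(cfg.tr_s * cfg.fs_hz)
    sampled = delayed[::step][: cfg.volumes_per_run]
    return (sampled - sampled.mean()) / sampled.std()


def simulate_session(
    cfg: SyntheticConfig,
) -> tuple[list[EegRecording], dict[str, list[RoiBoldSeries]], list[TaskEvent], SessionTruth]:
    """Simulate one full session.

    Returns
    -------
    runs : list of EegRecording
        One EEG recording per run.
    bolds : dict roi_label -> list of RoiBoldSeries
        Target ("VS") and control ("VC", "PMC", "STN") series, one per run,
        each z-scored at the native volume rate.
    events : list of TaskEvent
    truth : SessionTruth
        Ground-truth envelopes, drives and source parameters.
    """
    if not cfg.sources:
        raise ValueError("at least one source is required")
    events = make_task_events(cfg)
    labels = [f"e{i + 1}" for i in range(cfg.n_channels)]
    n = cfg.samples_per_run

    runs: list[EegRecording] = []
    bolds: dict[str, list[RoiBoldSeries]] = {TARGET_ROI: []}
    for roi in CONTROL_ROIS:
        bolds[roi] = []
    envelopes: dict[str, np.ndarray] = {}
    drives: dict[str, np.ndarray] = {}

    for k, run_id in enumerate(cfg.run_ids()):
        src_rng = _rng(cfg.seed, _TAG_SOURCE, k)
        eeg = np.zeros((cfg.n_channels, n))
        env_run = np.zeros((len(cfg.sources), n))
        for j, src in enumerate(cfg.sources):
            lo = src.center_freq_hz - src.bandwidth_hz / 2
            hi = src.center_freq_hz + src.bandwidth_hz / 2
            osc = _band_oscillation(src_rng, n, cfg.fs_hz, max(lo, 0.1), hi)
            gain = _gain_profile(cfg, events, run_id, src) * src.baseline_amp
            env_run[j] = gain * np.abs(signal.hilbert(osc))
            eeg += np.outer(src.spatial_pattern, gain * osc)
        noise_rng = _rng(cfg.seed, _TAG_EEG_NOISE, k)
        if cfg.eeg_noise.pink_sd > 0:
            eeg += cfg.eeg_noise.pink_sd * _pink_noise(noise_rng, (cfg.n_channels, n), cfg.fs_hz)
        if cfg.eeg_noise.white_sd > 0:
            eeg += cfg.eeg_noise.white_sd * noise_rng.standard_normal((cfg.n_channels, n))
        runs.append(EegRecording(eeg, labels, cfg.fs_hz, run_id))

        drive = _drive_to_bold(cfg, env_run[0], cfg.sources[0].coupling_exponent)
        bold_rng = _rng(cfg.seed, _TAG_BOLD_NOISE, k)
        noisy = drive + cfg.bold_noise_sd * bold_rng.standard_normal(cfg.volumes_per_run)
        noisy = (noisy - noisy.mean()) / noisy.std()
        bolds[TARGET_ROI].append(
            RoiBoldSeries(noisy, 1 / cfg.tr_s, TARGET_ROI, "target", run_id)
        )
        ctrl_rng = _rng(cfg.seed, _TAG_CONTROL, k)
        for roi in CONTROL_ROIS:
            series = cfg.control_coupling * drive + ctrl_rng.standard_normal(cfg.volumes_per_run)
            series = (series - series.mean()) / series.std()
            bolds[roi].append(RoiBoldSeries(series, 1 / cfg.tr_s, roi, "control", run_id))

        envelopes[run_id] = env_run
        drives[run_id] = drive

    truth = SessionTruth(
        config=cfg,
        envelopes=envelopes,
        drive=drives,
        patterns=np.stack([s.spatial_pattern for s in cfg.sources]),
        center_freqs_hz=np.array([s.center_freq_hz for s in cfg.sources]),
        win_gains=np.array([s.win_gain for s in cfg.sources]),
        loss_gains=np.array([s.loss_gain for s in cfg.sources]),
        seed=cfg.seed,
    )
    return runs, bolds, events, truth


def oracle_envelope_r(truth: SessionTruth, bold: RoiBoldSeries) -> float:
    """Noise-ceiling correlation for one run.

    Recomputes the HRF-convolved, delayed drive from the stored ground-truth
    envelope and correlates it with the (noisy) target BOLD.  No decoder can
    beat this on the same data, so it bounds the trained model's r.
    """
    cfg = truth.config
    if bold.run_id not in truth.envelopes:
        raise ValueError(f"unknown run {bold.run_id!r}")
    drive = _drive_to_bold(
        cfg, truth.envelopes[bold.run_id][0], cfg.sources[0].coupling_exponent
    )
    if drive.size != bold.n_samples:
        raise RuntimeError("resampled drive length does not match BOLD length")
    return float(np.corrcoef(drive, bold.values)[0, 1])


# ---------------------------------------------------------------------------
# container I/O


def write_session(
    out_dir: str | Path,
    runs: list[EegRecording],
    bolds: dict[str, list[RoiBoldSeries]],
    events: list[TaskEvent],
    truth: SessionTruth | None = None,
) -> Path:
    """Write a session to ``out_dir`` (HDF5 + BIDS-style events.tsv + JSON).

    Layout: ``session.h5`` with /run<k>/eeg [C x T] and /run<k>/bold/<roi>
    [V]; file attributes fs, tr and channel_labels.  Events go to
    ``events.tsv`` (onset, duration, trial_type, run); the ground truth, if
    given, to ``truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5_path = out_dir / "session.h5"
    with h5py.File(h5_path, "w") as f:
        f.attrs["fs"] = runs[0].fs_hz
        f.attrs["channel_labels"] = runs[0].channel_labels
        for k, rec in enumerate(runs):
            grp = f.create_group(f"run{k + 1}")
            grp.create_dataset("eeg", data=rec.data)
            bg = grp.create_group("bold")
            for roi, series_list in bolds.items():
                series = series_list[k]
                ds = bg.create_dataset(roi, data=series.values)
                ds.attrs["role"] = series.role
                f.attrs["tr"] = 1 / series.fs_hz
    rows = [
        {"onset": ev.onset_s, "duration": ev.duration_s,
         "trial_type": ev.outcome, "run": ev.run_id}
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(out_dir / "events.tsv", sep="\t", index=False)
    if truth is not None:
        payload = {
            "patterns": truth.patterns.tolist(),
            "center_freqs_hz": truth.center_freqs_hz.tolist(),
            "win_gains": truth.win_gains.tolist(),
            "loss_gains": truth.loss_gains.tolist(),
            "seed": truth.seed,
        }
        (out_dir / "truth.json").write_text(json.dumps(payload, indent=2))
    return h5_path


def load_session(
    session_dir: str | Path,
) -> tuple[list[EegRecording], dict[str, list[RoiBoldSeries]], list[TaskEvent]]:
    """Read back a session container written by :func:`write_session`."""
    session_dir = Path(session_dir)
    runs: list[EegRecording] = []
    bolds: dict[str, list[RoiBoldSeries]] = {}
    with h5py.File(session_dir / "session.h5", "r") as f:
        fs = float(f.attrs["fs"])
        tr = float(f.attrs["tr"])
        labels = [str(x) for x in f.attrs["channel_labels"]]
        run_keys = sorted(f.keys(), key=lambda s: int(s.removeprefix("run")))
        for key in run_keys:
            runs.append(EegRecording(f[key]["eeg"][()], labels, fs, key))
            for roi in f[key]["bold"]:
                ds = f[key]["bold"][roi]
                bolds.setdefault(roi, []).append(
                    RoiBoldSeries(ds[()], 1 / tr, roi, str(ds.attrs["role"]), key)
                )
    df = pd.read_csv(session_dir / "events.tsv", sep="\t")
    counters: dict[str, int] = {}
    events = []
    for row in df.itertuples():
        idx = counters.get(row.run, 0)
        counters[row.run] = idx + 1
        events.append(TaskEvent(run_id=row.run, trial_index=idx, onset_s=row.onset,
                                duration_s=row.duration, outcome=row.trial_type))
    return runs, bolds, events
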
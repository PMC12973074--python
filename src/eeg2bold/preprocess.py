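"""Final-stage conditioning and EEG-BOLD alignment.

The pipeline contract: signals are z-scored per run, the EEG is
(optionally) band-passed and re-referenced, both modalities are brought to
a common 100 Hz rate, and the EEG is advanced by the 6 s hemodynamic delay
so that the BOLD sample at time t is paired with the EEG at t - 6 s.
Training windows are then drawn at random start indices from the aligned
pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .datatypes import EegRecording, RoiBoldSeries

__all__ = [
    "AlignedPair",
    "TrainingWindow",
    "zscore",
    "common_average_reference",
    "bandpass",
    "align_pair",
    "extract_windows",
]

COMMON_FS_HZ = 100.0
HRF_DELAY_S = 6.0
DEFAULT_BAND_HZ = (0.5, 45.0)


@dataclass
class AlignedPair:
    """EEG and BOLD for one run on a common clock after the hemodynamic shift.

    ``eeg.data[:, i]`` is paired with ``bold.values[i]``; the EEG sample
    physically precedes the BOLD sample by ``hrf_delay_s``.
    """

    eeg: EegRecording
    bold: RoiBoldSeries
    fs_hz: float
    hrf_delay_s: float

    def __post_init__(self) -> None:
        if self.eeg.n_samples != self.bold.n_samples:
            raise ValueError("aligned EEG and BOLD must have equal lengths")
        if self.eeg.fs_hz != self.fs_hz or self.bold.fs_hz != self.fs_hz:
            raise ValueError("aligned pair members must share fs_hz")

    @property
    def n_samples(self) -> int:
        return self.eeg.n_samples


@dataclass
class TrainingWindow:
    """One (X, y) training pair: a channels x L EEG slice and length-L BOLD."""

    X: np.ndarray
    y: np.ndarray
    start_index: int
    run_id: str

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.y.size:
            raise ValueError("X and y must cover the same samples")


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Per-channel standardisation to mean 0, SD 1.

    Constant channels are mapped to all-zeros rather than NaN so that flat
    reference or bad channels pass through harmlessly.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 2:
        raise ValueError("need at least 2 samples to z-score")
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mean, sd, out=out, where=sd > 0)
    return out


def common_average_reference(eeg: EegRecording) -> EegRecording:
    """Re-reference to the common average montage (zero mean across channels)."""
    if eeg.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return EegRecording(data, eeg.channel_labels, eeg.fs_hz, eeg.run_id)


def bandpass(eeg: EegRecording, lo_hz: float = DEFAULT_BAND_HZ[0],
             hi_hz: float = DEFAULT_BAND_HZ[1], order: int = 4) -> EegRecording:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyq = eeg.fs_hz / 2
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError(f"band ({lo_hz}, {hi_hz}) must lie inside (0, {nyq})")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="band", fs=eeg.fs_hz, output="sos")
    data = signal.sosfiltfilt(sos, eeg.data, axis=1)
    return EegRecording(data, eeg.channel_labels, eeg.fs_hz, eeg.run_id)


def _resample_eeg(eeg: EegRecording, fs_common: float) -> EegRecording:
    if eeg.fs_hz == fs_common:
        return eeg
    if eeg.fs_hz < fs_common:
        raise ValueError("EEG rate below the common rate; upsampling EEG unsupported")
    n_out = round(eeg.n_samples * fs_common / eeg.fs_hz)
    data = signal.resample_poly(
        eeg.data, round(fs_common), round(eeg.fs_hz), axis=1
    )[:, :n_out]
    return EegRecording(data, eeg.channel_labels, fs_common, eeg.run_id)


def _interpolate_bold(bold: RoiBoldSeries, fs_common: float, kind: str) -> RoiBoldSeries:
    if bold.fs_hz == fs_common:
        return bold
    t_native = np.arange(bold.n_samples) / bold.fs_hz
    t_new = np.arange(0, t_native[-1] + 0.5 / fs_common, 1 / fs_common)
    t_new = t_new[t_new <= t_native[-1]]
    if kind == "cubic":
        values = CubicSpline(t_native, bold.values)(t_new)
    elif kind == "linear":
        values = np.interp(t_new, t_native, bold.values)
    else:
        raise ValueError("interpolation kind must be 'cubic' or 'linear'")
    return RoiBoldSeries(values, fs_common, bold.roi_label, bold.role, bold.run_id)


def align_pair(eeg: EegRecording, bold: RoiBoldSeries,
               fs_common: float = COMMON_FS_HZ, delay_s: float = HRF_DELAY_S,
               interpolation: str = "cubic") -> AlignedPair:
    """Resample both modalities to ``fs_common`` and apply the hemodynamic shift.

    The EEG is anti-alias filtered and decimated (polyphase) if needed; the
    BOLD series is cubic-spline interpolated up to the common rate.  The
    EEG is then advanced by ``delay_s``: sample i of the returned pair
    holds EEG at t = i/fs and BOLD at t = i/fs + delay_s, and the uncovered
    ends are trimmed, never padded.
    """
    eeg_c = _resample_eeg(eeg, fs_common)
    bold_c = _interpolate_bold(bold, fs_common, interpolation)
    shift = round(delay_s * fs_common)
    n = min(eeg_c.n_samples, bold_c.n_samples)
    if shift >= n:
        raise ValueError("delay exceeds the recording length")
    eeg_data = eeg_c.data[:, : n - shift]
    bold_vals = bold_c.values[shift:n]
    return AlignedPair(
        eeg=EegRecording(eeg_data, eeg_c.channel_labels, fs_common, eeg.run_id),
        bold=RoiBoldSeries(bold_vals, fs_common, bold.roi_label, bold.role, bold.run_id),
        fs_hz=fs_common,
        hrf_delay_s=delay_s,
    )


def extract_windows(pair: AlignedPair, window_s: float, n_windows: int,
                    seed: int) -> list[TrainingWindow]:
    """Draw ``n_windows`` random training windows from one aligned run.

    Start indices are uniform over [0, T - L] with L = window_s * fs;
    windows may overlap and never cross the run boundary.
    """
    length = round(window_s * pair.fs_hz)
    if length > pair.n_samples:
        raise ValueError("window longer than the aligned recording")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, pair.n_samples - length + 1, size=n_windows)
    return [
        TrainingWindow(
            X=pair.eeg.data[:, s: s + length],
            y=pair.bold.values[s: s + length],
            start_index=int(s),
            run_id=pair.eeg.run_id,
        )
        for s in starts
    ]
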
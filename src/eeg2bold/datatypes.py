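"""Core in-memory containers shared across the pipeline.

One run of multichannel EEG, one ROI BOLD series per run, and the trial
event table are the three inputs every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EegRecording", "RoiBoldSeries", "TaskEvent"]


@dataclass
class EegRecording:
    """One run of multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Channel-major signal matrix.
    channel_labels : list of str
        One label per row of ``data`` (e1...eC by convention).
    fs_hz : float
        Sampling rate in Hz.
    run_id : str
        Identifier of the acquisition run.
    """

    data: np.ndarray
    channel_labels: list[str]
    fs_hz: float
    run_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class RoiBoldSeries:
    """One ROI's BOLD time series for one run.

    ``role`` distinguishes the regression target ("target", the ventral
    striatum) from specificity-control regions ("control").  The native
    sampling rate is 1/TR (0.5 Hz at TR = 2 s); after interpolation to the
    common rate it becomes 100 Hz.
    """

    values: np.ndarray
    fs_hz: float
    roi_label: str
    role: str = "target"
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.role not in ("target", "control"):
            raise ValueError("role must be 'target' or 'control'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class TaskEvent:
    """One gambling-task trial outcome event.

    ``onset_s`` is the feedback onset in seconds from run start;
    ``outcome`` is "win" or "loss"; ``magnitude`` is the stake (5 or 25).
    """

    run_id: str
    trial_index: int
    onset_s: float
    duration_s: float
    outcome: str
    magnitude: int = 25

    def __post_init__(self) -> None:
        if self.outcome not in ("win", "loss"):
            raise ValueError("outcome must be 'win' or 'loss'")
        if self.magnitude not in (5, 25):
            raise ValueError("magnitude must be 5 or 25")
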
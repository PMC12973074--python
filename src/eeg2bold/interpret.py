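"""Spatio-spectral read-out of the trained compact block.

Each branch of the compact block is a spatial filter followed by a temporal
band filter.  Branch importance is measured by ablation: zero one branch's
envelope output and record the drop in held-out correlation.  Raw spatial
filters are not physiologically interpretable, so the reported spatial
pattern is the forward-model projection C_x w (channel covariance of the
evaluation EEG applied to the filter weights), unit-normalized.  The
frequency profile is the magnitude response of the branch's temporal kernel
weighted by the amplitude spectrum of the spatially filtered signal,
max-normalized; its resolution is bounded below by fs / kernel length
(~2 Hz for a 51-tap kernel at 100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import EegRecording
from .model import ModelHandle
from .nn import pearson_batch
from .preprocess import AlignedPair
from .training import predict_series

__all__ = [
    "BranchProfile",
    "average_profiles",
    "branch_importance",
    "branch_profile",
    "top_branches_report",
]

_NFFT = 512


@dataclass
class BranchProfile:
    """One branch's contribution summary."""

    branch_id: int
    importance: float
    spatial_pattern: np.ndarray  # unit norm, per channel
    freq_profile: np.ndarray     # in [0, 1], on freq_grid_hz
    freq_grid_hz: np.ndarray

    @property
    def peak_freq_hz(self) -> float:
        return float(self.freq_grid_hz[int(np.argmax(self.freq_profile))])


def _mean_r(model: ModelHandle, eval_pairs: list[AlignedPair],
            window_s: float) -> float:
    rs = []
    for pair in eval_pairs:
        pred = predict_series(model, pair, window_s)
        rs.append(pearson_batch(pred[None], pair.bold.values[None])[0])
    return float(np.mean(rs))


def branch_importance(model: ModelHandle, eval_pairs: list[AlignedPair],
                      window_s: float) -> np.ndarray:
    """Held-out delta-r from ablating each branch in turn.

    importance[b] = r(full model) - r(model with branch b's compact output
    zeroed), averaged over the evaluation pairs.
    """
    if not eval_pairs:
        raise ValueError("need at least one evaluation pair")
    n_branches = model.config.n_branches
    model.set_branch_mask(None)
    r_full = _mean_r(model, eval_pairs, window_s)
    importance = np.empty(n_branches)
    for b in range(n_branches):
        mask = np.ones(n_branches)
        mask[b] = 0.0
        model.set_branch_mask(mask)
        importance[b] = r_full - _mean_r(model, eval_pairs, window_s)
    model.set_branch_mask(None)
    return importance


def branch_profile(model: ModelHandle, branch_id: int, eval_eeg: EegRecording,
                   importance: float = np.nan) -> BranchProfile:
    """Forward-model spatial pattern and spectral profile of one branch."""
    if not 0 <= branch_id < model.config.n_branches:
        raise ValueError(f"branch {branch_id} out of range")
    w = model.spatial.weight.data[branch_id, :, 0]
    if w.size != eval_eeg.n_channels:
        raise ValueError("model channel count does not match the evaluation EEG")
    cov = np.cov(eval_eeg.data)
    pattern = cov @ w
    norm = np.linalg.norm(pattern)
    if norm > 0:
        pattern = pattern / norm

    fs = eval_eeg.fs_hz
    grid = np.fft.rfftfreq(_NFFT, d=1.0 / fs)
    kernel = model.band.weight.data[branch_id]
    response = np.abs(np.fft.rfft(kernel, n=_NFFT))
    filtered = w @ eval_eeg.data
    f_psd, psd = signal.welch(filtered, fs=fs, nperseg=min(_NFFT, filtered.size))
    amplitude = np.interp(grid, f_psd, np.sqrt(psd))
    profile = response * amplitude
    peak = profile.max()
    if peak > 0:
        profile = profile / peak
    return BranchProfile(branch_id=branch_id, importance=importance,
                         spatial_pattern=pattern, freq_profile=profile,
                         freq_grid_hz=grid)


def top_branches_report(fold_models: list[ModelHandle],
                        eval_pairs: list[AlignedPair], window_s: float,
                        k: int = 3) -> list[BranchProfile]:
    """Rank branches per fold by ablation importance and average by rank.

    Rank-1 profiles are averaged with rank-1 profiles across folds, and so
    on.  Spatial patterns are sign-ambiguous, so before averaging each
    fold's pattern is flipped to match the orientation of the across-fold
    consensus.
    """
    if not fold_models:
        raise ValueError("need at least one fold model")
    if len(fold_models) != len(eval_pairs):
        raise ValueError("one evaluation pair per fold model is required")
    n_branches = fold_models[0].config.n_branches
    if k > n_branches:
        raise ValueError("k cannot exceed the number of branches")

    per_rank: list[list[BranchProfile]] = [[] for _ in range(k)]
    for model, pair in zip(fold_models, eval_pairs):
        imp = branch_importance(model, [pair], window_s)
        order = np.argsort(imp)[::-1]
        for rank in range(k):
            b = int(order[rank])
            per_rank[rank].append(
                branch_profile(model, b, pair.eeg, importance=float(imp[b]))
            )

    return [average_profiles(profiles, rank) for rank, profiles in enumerate(per_rank)]


def average_profiles(profiles: list[BranchProfile], rank: int = 0) -> BranchProfile:
    """Average same-rank profiles across folds with sign alignment.

    Spatial filters (and hence patterns) are sign-ambiguous, so each fold's
    pattern is flipped to the orientation of the across-fold consensus
    before averaging; the result is invariant to flipping any input
    pattern's sign.
    """
    patterns = np.stack([p.spatial_pattern for p in profiles])
    ref = patterns[0]
    signs = np.where(patterns @ ref >= 0, 1.0, -1.0)
    # second pass against the consensus mean handles a poor first fold
    consensus = (patterns * signs[:, None]).mean(axis=0)
    signs = np.where(patterns @ consensus >= 0, 1.0, -1.0)
    mean_pattern = (patterns * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean_pattern)
    if norm > 0:
        mean_pattern = mean_pattern / norm
    mean_profile = np.stack([p.freq_profile for p in profiles]).mean(axis=0)
    peak = mean_profile.max()
    if peak > 0:
        mean_profile = mean_profile / peak
    return BranchProfile(
        branch_id=-1 - rank,  # synthetic id: a rank, not a single branch
        importance=float(np.mean([p.importance for p in profiles])),
        spatial_pattern=mean_pattern,
        freq_profile=mean_profile,
        freq_grid_hz=profiles[0].freq_grid_hz,
    )
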
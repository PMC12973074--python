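"""Regularized linear reference model on band-power features.

The baseline receives exactly the same fold splits and aligned pairs as
the deep model (the fairness condition for the DL-vs-linear comparison)
but sees the EEG only through a fixed feature bank: per channel and
canonical band (delta 1-4, theta 4-8, alpha 8-13, beta 13-30 Hz), the
signal is band-passed, squared, smoothed over 1 s, log-transformed and
z-scored.  Ridge regression maps the instantaneous feature vector to the
aligned BOLD sample; the penalty is chosen by inner 5-fold cross-validated
correlation on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.linear_model import Ridge

from .datatypes import EegRecording
from .preprocess import AlignedPair, zscore
from .training import FoldSpec

__all__ = [
    "DEFAULT_BANDS",
    "DEFAULT_RIDGE_GRID",
    "BandPowerFeatures",
    "BaselineFold",
    "bandpower_features",
    "fit_predict_linear",
    "train_fold_linear",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 4.0),    # delta
    (4.0, 8.0),    # theta
    (8.0, 13.0),   # alpha
    (13.0, 30.0),  # beta
)
DEFAULT_RIDGE_GRID: tuple[float, ...] = (1e-1, 1e0, 1e1, 1e2, 1e3, 1e4)


@dataclass
class BandPowerFeatures:
    """samples x (channels * bands) feature matrix with its band edges."""

    features: np.ndarray
    band_edges: tuple[tuple[float, float], ...]
    fs_hz: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class BaselineFold:
    """Held-out predictions of the linear model for one fold."""

    fold: FoldSpec
    y_true: np.ndarray
    y_pred: np.ndarray
    fs_hz: float
    penalty: float


def bandpower_features(eeg: EegRecording,
                       bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
                       smooth_s: float = 1.0) -> BandPowerFeatures:
    """Log band-power envelope features, z-scored per column."""
    nyq = eeg.fs_hz / 2
    for lo, hi in bands:
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band ({lo}, {hi}) outside (0, {nyq})")
    win = max(round(smooth_s * eeg.fs_hz), 1)
    kernel = np.ones(win) / win
    cols = []
    for lo, hi in bands:
        sos = signal.butter(4, [lo, hi], btype="band", fs=eeg.fs_hz, output="sos")
        filtered = signal.sosfiltfilt(sos, eeg.data, axis=1)
        power = filtered ** 2
        smoothed = signal.fftconvolve(power, kernel[None, :], mode="same", axes=1)
        cols.append(np.log(np.maximum(smoothed, 1e-12)))
    feats = np.concatenate(cols, axis=0)  # (bands*channels, samples)
    feats = zscore(feats, axis=1).T
    return BandPowerFeatures(feats, tuple(bands), eeg.fs_hz)


def _cv_correlation(features: np.ndarray, y: np.ndarray, alpha: float,
                    n_splits: int) -> float:
    """Mean held-out Pearson r over contiguous inner folds."""
    n = y.size
    edges = np.linspace(0, n, n_splits + 1, dtype=int)
    rs = []
    for i in range(n_splits):
        test = np.zeros(n, dtype=bool)
        test[edges[i]: edges[i + 1]] = True
        model = Ridge(alpha=alpha)
        model.fit(features[~test], y[~test])
        pred = model.predict(features[test])
        if pred.std() == 0 or y[test].std() == 0:
            rs.append(0.0)
        else:
            rs.append(np.corrcoef(pred, y[test])[0, 1])
    return float(np.mean(rs))


def fit_predict_linear(features_train: np.ndarray, y_train: np.ndarray,
                       features_test: np.ndarray,
                       ridge_grid: tuple[float, ...] = DEFAULT_RIDGE_GRID,
                       n_inner_splits: int = 5) -> tuple[np.ndarray, float]:
    """Ridge fit with inner-CV penalty selection; returns test predictions."""
    if len(ridge_grid) < 2:
        raise ValueError("ridge_grid needs at least 2 penalties")
    if features_train.shape[0] != y_train.size:
        raise ValueError("features_train and y_train lengths differ")
    if np.allclose(features_train.std(axis=0), 0):
        raise ValueError("degenerate (rank-0) feature matrix")
    scores = [_cv_correlation(features_train, y_train, a, n_inner_splits)
              for a in ridge_grid]
    best = float(ridge_grid[int(np.argmax(scores))])
    model = Ridge(alpha=best)
    model.fit(features_train, y_train)
    return model.predict(features_test), best


def train_fold_linear(pairs: dict[str, AlignedPair], fold: FoldSpec,
                      bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
                      smooth_s: float = 1.0,
                      ridge_grid: tuple[float, ...] = DEFAULT_RIDGE_GRID) -> BaselineFold:
    """Fit the linear baseline on a fold's train runs, predict its test run.

    The validation run joins the training data here: ridge's inner CV
    replaces epoch-level early stopping, so no run needs to be held back.
    """
    train_runs = (*fold.train_runs, fold.validation_run)
    feats, ys = [], []
    for run in train_runs:
        pair = pairs[run]
        feats.append(bandpower_features(pair.eeg, bands, smooth_s).features)
        ys.append(pair.bold.values)
    test_pair = pairs[fold.test_run]
    f_test = bandpower_features(test_pair.eeg, bands, smooth_s).features
    y_pred, penalty = fit_predict_linear(
        np.concatenate(feats), np.concatenate(ys), f_test, ridge_grid
    )
    return BaselineFold(fold=fold, y_true=test_pair.bold.values.copy(),
                        y_pred=y_pred, fs_hz=test_pair.fs_hz, penalty=penalty)
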
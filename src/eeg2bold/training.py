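"""Fold construction and the window-sampled training loop.

Cross-validation is run-level: each fold holds out one run for testing,
reserves one further run for early-stopping validation, and trains on the
rest.  Every epoch draws a fresh set of random 160 s windows from the
training runs (fewer/shorter at the reduced desk-scale profile), optimises
the weighted MSE - Pearson loss with AdamW under a single-cycle cosine
schedule, and monitors validation loss on a fixed window set; training
halts when validation loss has sat above its running best while training
loss kept falling for ``patience`` consecutive epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import ModelConfig, ModelHandle, build_model
from .nn import AdamW, cosine_annealing_lr, mse_corr_loss
from .preprocess import AlignedPair, extract_windows

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "TrainConfig",
    "FoldSpec",
    "TrainedFold",
    "TrainingDivergence",
    "compute_loss",
    "make_folds",
    "early_stop_check",
    "train_fold",
    "predict_series",
]


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class LossConfig:
    """MSE / correlation mixing weights (0.9 / 0.1 by default)."""

    weight_mse: float = 0.9
    weight_corr: float = 0.1

    def __post_init__(self) -> None:
        if self.weight_mse < 0 or self.weight_corr < 0:
            raise ValueError("loss weights must be >= 0")
        if self.weight_mse == 0 and self.weight_corr == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters; defaults are the full-scale profile."""

    learning_rate: float = 3e-5
    weight_decay: float = 3e-4
    batch_size: int = 32
    scheduler_t_max_epochs: int = 50
    early_stop_patience_epochs: int = 15
    max_epochs: int = 200
    windows_per_epoch: int = 256
    window_s: float = 160.0
    augment_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "weight_decay", "batch_size",
                     "scheduler_t_max_epochs", "early_stop_patience_epochs",
                     "max_epochs", "windows_per_epoch", "window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience_epochs >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.augment_noise_sd < 0:
            raise ValueError("augment_noise_sd must be >= 0")


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold: disjoint test / validation / train runs."""

    fold_id: int
    test_run: str
    validation_run: str
    train_runs: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        members = {self.test_run, self.validation_run, *self.train_runs}
        if len(members) != 2 + len(self.train_runs):
            raise ValueError("test, validation and train runs must be disjoint")


@dataclass
class TrainedFold:
    """Output of one fold: best-validation-epoch model plus held-out traces."""

    fold: FoldSpec
    model: ModelHandle
    train_losses: list[float]
    val_losses: list[float]
    stop_reason: str
    y_true: np.ndarray
    y_pred: np.ndarray
    fs_hz: float


def compute_loss(y_true: np.ndarray, y_pred: np.ndarray,
                 cfg: LossConfig = LossConfig()) -> float:
    """weight_mse * MSE + weight_corr * (-r) for one window pair."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    if y_true.ndim == 1 and y_true.size < 2:
        raise ValueError("need at least 2 samples")
    value, _ = mse_corr_loss(y_pred, y_true, cfg.weight_mse, cfg.weight_corr)
    return value


def make_folds(run_ids: list[str], n_folds: int, seed: int) -> list[FoldSpec]:
    """Sample ``n_folds`` held-out test runs without replacement.

    Each fold additionally reserves one seeded-random non-test run for
    early-stopping validation; the remaining runs train the model.
    """
    if len(run_ids) < 3:
        raise ValueError("need at least 3 runs (train + validation + test)")
    if n_folds > len(run_ids):
        raise ValueError("n_folds cannot exceed the number of runs")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    order = list(rng.permutation(run_ids))
    folds = []
    for i, test_run in enumerate(order[:n_folds]):
        rest = [r for r in run_ids if r != test_run]
        val = rest[int(rng.integers(len(rest)))]
        train = tuple(r for r in rest if r != val)
        folds.append(FoldSpec(fold_id=i, test_run=test_run, validation_run=val,
                              train_runs=train, seed=seed))
    return folds


def early_stop_check(train_losses: list[float], val_losses: list[float],
                     patience: int) -> bool:
    """Early-stopping rule.

    True iff, for each of the last ``patience`` epochs, the validation loss
    exceeded its running best (no new minimum) while the training loss was
    non-increasing epoch over epoch.
    """
    if len(val_losses) != len(train_losses) or not val_losses:
        raise ValueError("histories must be non-empty and equal length")
    n = len(val_losses)
    if n < patience + 1:
        return False
    for i in range(n - patience, n):
        if val_losses[i] <= min(val_losses[:i]):
            return False
        if train_losses[i] > train_losses[i - 1]:
            return False
    return True


def _draw_epoch_windows(pairs: dict[str, AlignedPair], runs: tuple[str, ...] | list[str],
                        window_s: float, n_windows: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stack ``n_windows`` random windows drawn uniformly across runs."""
    run_choice = rng.integers(len(runs), size=n_windows)
    xs, ys = [], []
    for k, run in enumerate(runs):
        count = int((run_choice == k).sum())
        if count == 0:
            continue
        wins = extract_windows(pairs[run], window_s, count,
                               seed=int(rng.integers(2 ** 31)))
        xs += [w.X for w in wins]
        ys += [w.y for w in wins]
    perm = rng.permutation(len(xs))
    return np.stack(xs)[perm], np.stack(ys)[perm]


def _snapshot(model: ModelHandle) -> list[np.ndarray]:
    from .nn import BatchNorm1d

    arrs = [p.data.copy() for p in model.params()]
    for layer in model.body.layers:
        if isinstance(layer, BatchNorm1d):
            arrs += [layer.running_mean.copy(), layer.running_var.copy()]
    return arrs


def _restore(model: ModelHandle, arrs: list[np.ndarray]) -> None:
    from .nn import BatchNorm1d

    params = model.params()
    for p, a in zip(params, arrs):
        p.data[...] = a
    extra = arrs[len(params):]
    i = 0
    for layer in model.body.layers:
        if isinstance(layer, BatchNorm1d):
            layer.running_mean[...] = extra[i]
            layer.running_var[...] = extra[i + 1]
            i += 2


def train_fold(pairs: dict[str, AlignedPair], fold: FoldSpec,
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               loss_cfg: LossConfig = LossConfig()) -> TrainedFold:
    """Train one fold and return the best-validation model with test traces."""
    for run in (fold.test_run, fold.validation_run, *fold.train_runs):
        if run not in pairs:
            raise ValueError(f"run {run!r} not available in the aligned pairs")

    ss = np.random.SeedSequence([train_cfg.seed, fold.fold_id, 101])
    rng = np.random.default_rng(ss)
    model = build_model(model_cfg, seed=int(rng.integers(2 ** 31)))
    opt = AdamW(model.params(), lr=train_cfg.learning_rate,
                weight_decay=train_cfg.weight_decay)

    val_pair = pairs[fold.validation_run]
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_state = _snapshot(model)
    stop_reason = "max_epochs"

    for epoch in range(train_cfg.max_epochs):
        opt.lr = cosine_annealing_lr(train_cfg.learning_rate, epoch,
                                     train_cfg.scheduler_t_max_epochs)
        X, y = _draw_epoch_windows(pairs, fold.train_runs, train_cfg.window_s,
                                   train_cfg.windows_per_epoch, rng)
        batch_losses = []
        for a in range(0, X.shape[0], train_cfg.batch_size):
            xb, yb = X[a: a + train_cfg.batch_size], y[a: a + train_cfg.batch_size]
            if train_cfg.augment_noise_sd > 0:
                # white input noise regularises against memorising run-
                # specific EEG background
                xb = xb + train_cfg.augment_noise_sd * rng.standard_normal(xb.shape)
            pred = model.forward(xb)
            value, grad = mse_corr_loss(pred, yb, loss_cfg.weight_mse,
                                        loss_cfg.weight_corr)
            if not np.isfinite(value):
                raise TrainingDivergence(epoch)
            model.zero_grad()
            model.backward(grad)
            opt.step()
            batch_losses.append(value)
        train_losses.append(float(np.mean(batch_losses)))
        # validation loss on the full stitched validation run: one number
        # per epoch, far more stable than a handful of random windows
        val_pred = predict_series(model, val_pair, train_cfg.window_s)
        model.train()
        val_value, _ = mse_corr_loss(val_pred[None], val_pair.bold.values[None],
                                     loss_cfg.weight_mse, loss_cfg.weight_corr)
        val_losses.append(float(val_value))
        logger.info("fold %d epoch %d: train %.4f val %.4f", fold.fold_id,
                    epoch, train_losses[-1], val_losses[-1])
        if val_losses[-1] < best_val:
            best_val = val_losses[-1]
            best_state = _snapshot(model)
        if early_stop_check(train_losses, val_losses,
                            train_cfg.early_stop_patience_epochs):
            stop_reason = "early_stop"
            break

    _restore(model, best_state)
    model.eval()
    test_pair = pairs[fold.test_run]
    y_pred = predict_series(model, test_pair, train_cfg.window_s)
    return TrainedFold(
        fold=fold,
        model=model,
        train_losses=train_losses,
        val_losses=val_losses,
        stop_reason=stop_reason,
        y_true=test_pair.bold.values.copy(),
        y_pred=y_pred,
        fs_hz=test_pair.fs_hz,
    )


def predict_series(model: ModelHandle, pair: AlignedPair,
                   window_s: float, hop_fraction: int = 4) -> np.ndarray:
    """Predict the full run by tiling overlapping windows and averaging.

    Windows advance by ``window / hop_fraction``; averaging the overlapping
    predictions smooths the coarse temporal grid the pooled bottleneck
    imposes on any single window.
    """
    model.eval()
    length = round(window_s * pair.fs_hz)
    n = pair.n_samples
    if length > n:
        raise ValueError("window longer than the aligned run")
    hop = max(length // hop_fraction, 1)
    starts = list(range(0, n - length + 1, hop))
    if starts[-1] != n - length:
        starts.append(n - length)
    out = np.zeros(n)
    weight = np.zeros(n)
    for s in starts:
        pred = model.forward(pair.eeg.data[:, s: s + length])
        out[s: s + length] += pred
        weight[s: s + length] += 1.0
    return out / weight
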
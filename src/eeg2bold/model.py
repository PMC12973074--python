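"""Interpretable convolutional regression autoencoder (EEG window -> BOLD window).

The front end is a compact block of parallel spatio-spectral branches: each
branch applies a learnable spatial filter (a pointwise convolution over the
62 channels), a depthwise temporal convolution (kernel 51) that selects a
frequency band, a ReLU, and a second kernel-51 depthwise convolution that
smooths the rectified signal into a power-envelope-like series.  Spatial
and temporal convolutions in this block carry no bias, so each branch stays
a pure "spatial filter -> band filter -> power" chain that the
interpretability module can read out.

The branch envelopes are merged by a kernel-3 projection convolution and
passed through a three-block conv encoder (128 channels, batch norm, GeLU,
dropout 0.3, max-pool stride 8) and a mirrored decoder whose channel count
is reduced by a factor of 4, with x8 linear upsampling per block.  A final
linear upsampling restores the exact input length and a 1x1 convolution
yields the single-channel BOLD prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "ModelHandle", "build_model", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the full-scale profile."""

    n_channels: int = 62
    n_branches: int = 16
    temporal_kernel: int = 51
    projection_kernel: int = 3
    encoder_channels: int = 128
    encoder_kernel: int = 3
    n_encoder_blocks: int = 3
    pool_stride: int = 8
    dropout_rate: float = 0.3
    decoder_channel_reduction: int = 4
    norm: str = "batch"  # or "instance"
    filterbank_init: bool = True
    fs_hz: float = 100.0  # used only to place the initial filterbank

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_branches", "temporal_kernel", "projection_kernel",
                     "encoder_channels", "encoder_kernel", "n_encoder_blocks",
                     "decoder_channel_reduction"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pool_stride < 2:
            raise ValueError("pool_stride must be >= 2")
        if self.encoder_channels % self.decoder_channel_reduction:
            raise ValueError("encoder_channels must be divisible by the reduction factor")
        if self.norm not in ("batch", "instance"):
            raise ValueError("norm must be 'batch' or 'instance'")

    @property
    def decoder_channels(self) -> int:
        return self.encoder_channels // self.decoder_channel_reduction

    @property
    def min_length(self) -> int:
        return self.pool_stride ** self.n_encoder_blocks


def _norm_layer(cfg: ModelConfig, channels: int, name: str) -> nn.Module:
    if cfg.norm == "instance":
        return nn.InstanceNorm1d(channels, name=name)
    return nn.BatchNorm1d(channels, name=name)


class ModelHandle:
    """A built model: compact block + encoder/decoder body, with parameters.

    Use :func:`build_model` to construct one.  ``forward`` is deterministic
    when training mode is off (dropout disabled, batch norm on running
    statistics).
    """

    def __init__(self, config: ModelConfig, seed: int) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        cfg = config
        self.spatial = nn.Conv1d(cfg.n_channels, cfg.n_branches, 1, bias=False,
                                 rng=rng, name="spatial")
        self.band = nn.Conv1d(cfg.n_branches, cfg.n_branches, cfg.temporal_kernel,
                              groups=cfg.n_branches, bias=False, rng=rng, name="band")
        self.smooth = nn.Conv1d(cfg.n_branches, cfg.n_branches, cfg.temporal_kernel,
                                groups=cfg.n_branches, bias=False, rng=rng, name="smooth")
        self.compact = nn.Sequential(self.spatial, self.band, nn.ReLU(), self.smooth)
        if cfg.filterbank_init:
            self._init_filterbank()

        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        layers: list[nn.Module] = [
            nn.Conv1d(cfg.n_branches, cfg.encoder_channels, cfg.projection_kernel,
                      rng=rng, name="projection")
        ]
        for b in range(cfg.n_encoder_blocks):
            layers += [
                nn.Conv1d(cfg.encoder_channels, cfg.encoder_channels, cfg.encoder_kernel,
                          rng=rng, name=f"enc{b}"),
                _norm_layer(cfg, cfg.encoder_channels, f"enc{b}.norm"),
                nn.GeLU(),
                nn.Dropout(cfg.dropout_rate, rng=drop_rng),
                nn.MaxPool1d(cfg.pool_stride),
            ]
        in_ch = cfg.encoder_channels
        for b in range(cfg.n_encoder_blocks):
            layers += [
                nn.Conv1d(in_ch, cfg.decoder_channels, cfg.encoder_kernel,
                          rng=rng, name=f"dec{b}"),
                _norm_layer(cfg, cfg.decoder_channels, f"dec{b}.norm"),
                nn.GeLU(),
                nn.Dropout(cfg.dropout_rate, rng=drop_rng),
                nn.UpsampleLinear(cfg.pool_stride),
            ]
            in_ch = cfg.decoder_channels
        self._resize = nn.UpsampleTo()
        self.head = nn.Conv1d(cfg.decoder_channels, 1, 1, rng=rng, name="head")
        self.body = nn.Sequential(*layers, self._resize, self.head)
        self.training_mode = True
        self._branch_mask: np.ndarray | None = None

    def _init_filterbank(self) -> None:
        """Start the temporal kernels as a log-spaced Gabor filter bank.

        The compact block is designed to act as "band filter then power
        envelope"; initialising the band kernels as windowed sinusoids with
        log-spaced centre frequencies (2 Hz to 0.4 x Nyquist) and the
        smoothing kernels as unit-sum Hann windows places the model in that
        regime from the start instead of asking gradient descent to
        discover oscillatory kernels from white-noise initialisation.  All
        kernels remain fully trainable.
        """
        from scipy.signal.windows import hann

        cfg = self.config
        k = cfg.temporal_kernel
        t = (np.arange(k) - k // 2) / cfg.fs_hz
        f_hi = 0.4 * cfg.fs_hz / 2
        freqs = np.geomspace(2.0, max(f_hi, 2.5), cfg.n_branches)
        taper = hann(k)
        for b, f in enumerate(freqs):
            g = np.cos(2 * np.pi * f * t) * taper
            self.band.weight.data[b] = g / np.linalg.norm(g)
            self.smooth.weight.data[b] = taper / taper.sum()

    # -- mode and parameter plumbing ------------------------------------
    def params(self) -> list[nn.Param]:
        return self.compact.params() + self.body.params()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def train(self, mode: bool = True) -> "ModelHandle":
        self.training_mode = mode
        self.compact.train(mode)
        self.body.train(mode)
        return self

    def eval(self) -> "ModelHandle":
        return self.train(False)

    def zero_grad(self) -> None:
        self.compact.zero_grad()
        self.body.zero_grad()

    def set_branch_mask(self, mask: np.ndarray | None) -> None:
        """Multiply compact-block branch outputs by ``mask`` (ablation hook)."""
        if mask is not None:
            mask = np.asarray(mask, dtype=float).ravel()
            if mask.size != self.config.n_branches:
                raise ValueError("mask length must equal n_branches")
        self._branch_mask = mask

    # -- forward / backward ---------------------------------------------
    def _as_batch(self, X: np.ndarray) -> tuple[np.ndarray, bool]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return X[None], True
        if X.ndim == 3:
            return X, False
        raise ValueError("X must be (channels, L) or (batch, channels, L)")

    def forward_compact(self, X: np.ndarray) -> np.ndarray:
        """Branch envelope series, shape (n_branches, L) (or batched)."""
        xb, squeeze = self._as_batch(X)
        if xb.shape[1] != self.config.n_channels:
            raise ValueError(
                f"expected {self.config.n_channels} channels, got {xb.shape[1]}"
            )
        if xb.shape[2] < self.config.temporal_kernel:
            raise ValueError("window shorter than the temporal kernel")
        out = self.compact.forward(xb)
        if self._branch_mask is not None:
            out = out * self._branch_mask[None, :, None]
        return out[0] if squeeze else out

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predicted BOLD window, same temporal length as the input."""
        xb, squeeze = self._as_batch(X)
        if xb.shape[2] < self.config.min_length:
            raise ValueError(
                f"window length {xb.shape[2]} shorter than the receptive minimum "
                f"{self.config.min_length}"
            )
        z = self.forward_compact(xb)
        self._resize.target_length = xb.shape[2]
        y = self.body.forward(z)[:, 0, :]
        return y[0] if squeeze else y

    def backward(self, grad_y: np.ndarray) -> None:
        """Accumulate parameter gradients from d loss / d prediction."""
        grad = np.asarray(grad_y, dtype=float)
        if grad.ndim == 1:
            grad = grad[None]
        g = self.body.backward(grad[:, None, :])
        if self._branch_mask is not None:
            g = g * self._branch_mask[None, :, None]
        self.compact.backward(g)

    __call__ = forward


def build_model(config: ModelConfig, seed: int) -> ModelHandle:
    """Assemble the autoencoder with seeded weight initialisation."""
    return ModelHandle(config, seed)


def save_checkpoint(model: ModelHandle, path: str | Path) -> None:
    """Serialise weights plus config metadata to a single .npz file."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    # running norm statistics keep eval-mode forward reproducible
    stats = {}
    for j, layer in enumerate(model.body.layers):
        if isinstance(layer, nn.BatchNorm1d):
            stats[f"rm{j}"] = layer.running_mean
            stats[f"rv{j}"] = layer.running_var
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays, **stats)


def load_checkpoint(path: str | Path, config: ModelConfig | None = None) -> ModelHandle:
    """Rebuild a model from a checkpoint; fails loudly on config mismatch."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        stored = ModelConfig(**meta["config"])
        if config is not None and config != stored:
            raise ValueError("checkpoint config does not match the requested config")
        model = build_model(stored, meta["seed"])
        for i, p in enumerate(model.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint parameter shapes do not match config")
            p.data[...] = arr
        for j, layer in enumerate(model.body.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = data[f"rm{j}"]
                layer.running_var[...] = data[f"rv{j}"]
    return model
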
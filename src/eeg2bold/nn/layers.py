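"""Minimal 1-D conv-net layers with explicit reverse-mode gradients.

The translation model is a pure feed-forward chain, so instead of a general
autograd graph each layer caches what its backward pass needs and the
:class:`Sequential` container runs the chain in reverse.  Convolutions are
implemented as K shifted BLAS contractions (fast for the small kernels used
here); every layer's gradient is finite-difference checked in the test
suite.

Shapes follow the (batch, channels, length) convention throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Conv1d",
    "ReLU",
    "GeLU",
    "BatchNorm1d",
    "InstanceNorm1d",
    "Dropout",
    "MaxPool1d",
    "UpsampleLinear",
    "UpsampleTo",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Module:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def train(self, mode: bool = True) -> "Sequential":
        self.training = mode
        for layer in self.layers:
            layer.train(mode)
        return self


def _same_pad(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class Conv1d(Module):
    """Same-padded 1-D convolution (cross-correlation), stride 1.

    Supports ungrouped (groups=1) and depthwise (groups == in_channels ==
    out_channels) modes, the only two the model needs.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv") -> None:
        if groups not in (1, in_channels):
            raise ValueError("only groups=1 or depthwise convolutions are supported")
        if groups == in_channels and out_channels != in_channels:
            raise ValueError("depthwise convolution requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.depthwise = groups == in_channels and groups > 1
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * (1 if self.depthwise else in_channels)
        std = np.sqrt(2.0 / fan_in)
        if self.depthwise:
            w = rng.normal(0.0, std, size=(in_channels, kernel_size))
        else:
            w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        n, _, length = x.shape
        k = self.kernel_size
        pl, pr = _same_pad(k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._cache = xp
        w = self.weight.data
        if self.depthwise:
            y = np.zeros((n, self.out_channels, length))
            for j in range(k):
                y += w[None, :, j, None] * xp[:, :, j: j + length]
        else:
            acc = np.zeros((n, length, self.out_channels))
            for j in range(k):
                # (N, C_in, L) x (C_out, C_in) -> (N, L, C_out) via BLAS
                acc += np.tensordot(xp[:, :, j: j + length], w[:, :, j], axes=([1], [1]))
            y = np.ascontiguousarray(np.moveaxis(acc, 2, 1))
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._cache
        n, _, length = grad.shape
        k = self.kernel_size
        w = self.weight.data
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        if self.depthwise:
            for j in range(k):
                self.weight.grad[:, j] += (grad * xp[:, :, j: j + length]).sum(axis=(0, 2))
                dxp[:, :, j: j + length] += w[None, :, j, None] * grad
        else:
            for j in range(k):
                self.weight.grad[:, :, j] += np.tensordot(
                    grad, xp[:, :, j: j + length], axes=([0, 2], [0, 2])
                )
                dxp[:, :, j: j + length] += np.moveaxis(
                    np.tensordot(grad, w[:, :, j], axes=([1], [0])), 2, 1
                )
        pl, pr = _same_pad(k)
        return dxp[:, :, pl: xp.shape[2] - pr]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GeLU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._phi = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._phi

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return grad * (self._phi + x * pdf)


class BatchNorm1d(Module):
    """Normalise each channel over the batch and temporal axes."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn") -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(num_channels), f"{name}.gamma")
        self.beta = Param(np.zeros(num_channels), f"{name}.beta")
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
        self._m = x.shape[0] * x.shape[2]
        return self.gamma.data[None, :, None] * self._xhat + self.beta.data[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.data[None, :, None]
        if not self.training:
            return g * inv_std[None, :, None]
        gsum = g.sum(axis=(0, 2), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * g - gsum - xhat * gx)


class InstanceNorm1d(Module):
    """Normalise each (sample, channel) series over time; no running stats."""

    def __init__(self, num_channels: int, eps: float = 1e-5, name: str = "in") -> None:
        self.eps = eps
        self.gamma = Param(np.ones(num_channels), f"{name}.gamma")
        self.beta = Param(np.zeros(num_channels), f"{name}.beta")

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._m = x.shape[2]
        return self.gamma.data[None, :, None] * self._xhat + self.beta.data[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.data[None, :, None]
        gsum = g.sum(axis=2, keepdims=True)
        gx = (g * xhat).sum(axis=2, keepdims=True)
        return (inv_std / m) * (m * g - gsum - xhat * gx)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class MaxPool1d(Module):
    """Non-overlapping max pooling with floor length semantics."""

    def __init__(self, stride: int) -> None:
        if stride < 2:
            raise ValueError("pool stride must be >= 2")
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        n, c, length = x.shape
        l_out = length // s
        if l_out < 1:
            raise ValueError(f"length {length} too short for pool stride {s}")
        self._in_shape = x.shape
        blocks = x[:, :, : l_out * s].reshape(n, c, l_out, s)
        self._argmax = blocks.argmax(axis=3)
        return blocks.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        s = self.stride
        l_out = grad.shape[2]
        dblocks = np.zeros((n, c, l_out, s))
        np.put_along_axis(dblocks, self._argmax[..., None], grad[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, : l_out * s] = dblocks.reshape(n, c, l_out * s)
        return dx


class _LinearInterp(Module):
    """Shared machinery: linear interpolation from L_in to a target length."""

    def _plan(self, l_in: int, l_out: int) -> None:
        pos = (np.arange(l_out) + 0.5) * (l_in / l_out) - 0.5
        pos = np.clip(pos, 0.0, l_in - 1.0)
        i0 = np.floor(pos).astype(int)
        i1 = np.minimum(i0 + 1, l_in - 1)
        self._i0, self._i1 = i0, i1
        self._w1 = pos - i0
        self._l_in = l_in

    def _interp(self, x: np.ndarray) -> np.ndarray:
        return x[:, :, self._i0] * (1.0 - self._w1) + x[:, :, self._i1] * self._w1

    def _interp_back(self, grad: np.ndarray, shape: tuple) -> np.ndarray:
        dx = np.zeros(shape)
        np.add.at(dx, (slice(None), slice(None), self._i0), grad * (1.0 - self._w1))
        np.add.at(dx, (slice(None), slice(None), self._i1), grad * self._w1)
        return dx


class UpsampleLinear(_LinearInterp):
    """Upsample the temporal axis by an integer factor (linear interpolation)."""

    def __init__(self, factor: int) -> None:
        if factor < 1:
            raise ValueError("upsample factor must be >= 1")
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._plan(x.shape[2], x.shape[2] * self.factor)
        return self._interp(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self._interp_back(grad, self._shape)


class UpsampleTo(_LinearInterp):
    """Resize the temporal axis to an exact target length set per forward call."""

    def __init__(self) -> None:
        self.target_length: int | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.target_length is None:
            raise RuntimeError("target_length must be set before forward")
        self._shape = x.shape
        self._plan(x.shape[2], self.target_length)
        return self._interp(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self._interp_back(grad, self._shape)
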
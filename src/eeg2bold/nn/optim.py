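"""AdamW with decoupled weight decay and a single-cycle cosine LR schedule."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW", "cosine_annealing_lr"]


class AdamW:
    """Adam with decoupled weight decay (Loshchilov-Hutter update)."""

    def __init__(self, params: list[Param], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 3e-4) -> None:
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (
                (m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def cosine_annealing_lr(base_lr: float, epoch: int, t_max: int,
                        eta_min: float = 0.0) -> float:
    """Cosine decay from ``base_lr`` to ``eta_min`` over ``t_max`` epochs.

    A single half-cycle without restarts; epochs past ``t_max`` stay at the
    floor.
    """
    if epoch >= t_max:
        return eta_min
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + np.cos(np.pi * epoch / t_max))
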
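"""Fused training loss: weighted MSE minus Pearson correlation.

The loss per window is  w_mse * MSE(y, yhat) + w_corr * (-r(y, yhat)); the
correlation term is negated so the objective decreases as predictions align
with the target.  The batch loss is the mean over windows.  The analytic
gradient with respect to the prediction is returned alongside the value so
the model chain can be driven directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mse_corr_loss", "pearson_batch"]


def pearson_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for (N, L) arrays; zero-variance rows give r = 0."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = na * nb
    r = np.zeros(a.shape[0])
    ok = denom > 0
    r[ok] = (ac * bc).sum(axis=1)[ok] / denom[ok]
    return r


def mse_corr_loss(y_pred: np.ndarray, y_true: np.ndarray,
                  weight_mse: float = 0.9, weight_corr: float = 0.1
                  ) -> tuple[float, np.ndarray]:
    """Batch loss value and its gradient with respect to ``y_pred``.

    Both inputs are (N, L).  Returns ``(loss, dloss/dy_pred)``.
    """
    y_pred = np.atleast_2d(y_pred)
    y_true = np.atleast_2d(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError("y_pred and y_true must have equal shapes")
    n, length = y_pred.shape
    diff = y_pred - y_true
    mse = (diff * diff).mean(axis=1)

    pc = y_pred - y_pred.mean(axis=1, keepdims=True)
    tc = y_true - y_true.mean(axis=1, keepdims=True)
    np_norm = np.linalg.norm(pc, axis=1)
    nt_norm = np.linalg.norm(tc, axis=1)
    denom = np_norm * nt_norm
    ok = denom > 0
    r = np.zeros(n)
    r[ok] = (pc * tc).sum(axis=1)[ok] / denom[ok]

    loss = float((weight_mse * mse - weight_corr * r).mean())

    grad = weight_mse * 2.0 * diff / length
    # d r / d y_pred = (tc / (|pc||tc|)) - r * pc / |pc|^2 ; zero-variance rows
    # contribute no correlation gradient.
    dr = np.zeros_like(y_pred)
    if ok.any():
        dr[ok] = (tc[ok] / denom[ok, None]
                  - r[ok, None] * pc[ok] / (np_norm[ok, None] ** 2))
    grad -= weight_corr * dr
    return loss, grad / n
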
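"""Differentiable generalized Dice loss for the autodiff engine.

Single custom node: for label l (channel axis 1 of NCHW batches),
w_l = 1 / (sum g_l + eps),
GDL = 1 - (2 sum_l w_l sum g_l p_l + eps) / (sum_l w_l (sum g_l + sum p_l) + eps),
with all sums pooled over the batch.  Mirrors
:func:`tribrats.metrics.generalized_dice_loss` exactly (tested).
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, _track


def generalized_dice_loss(pred: Tensor, truth: np.ndarray, epsilon: float = 1e-6) -> Tensor:
    """GDL between predicted probabilities (N,L,H,W) and binary truth."""
    p = pred.data.astype(np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    L = p.shape[1]
    axes = (0, 2, 3)
    gsum = g.sum(axis=axes)  # (L,)
    psum = p.sum(axis=axes)
    inter = (g * p).sum(axis=axes)
    w = 1.0 / (gsum + epsilon)
    num = 2.0 * (w * inter).sum() + epsilon
    den = (w * (gsum + psum)).sum() + epsilon
    loss = 1.0 - num / den
    out_data = np.array(loss, dtype=np.float32)
    if not _track(pred):
        return Tensor(out_data)

    def backward(gy):
        # d loss / d p_i(l) = -2 [ w_l g_i D - (sum w inter + eps) w_l ] / D^2  * 2?  --
        # derivative of 1 - num/den with num = 2(S_I + eps), den = D:
        #   d = -(num' den - num den') / den^2
        #   num' wrt p_i = 2 w_l g_i ; den' wrt p_i = w_l
        wl = w.reshape(1, L, 1, 1)
        dnum = 2.0 * wl * g
        dden = wl * np.ones_like(g)
        dp = -(dnum * den - num * dden) / (den * den)
        pred.accumulate((gy * dp).astype(np.float32))

    return Tensor(out_data, (pred,), backward)
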
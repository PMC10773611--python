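"""Segmentation metrics: confusion counts, pixel accuracy, DSC, and the
generalized Dice loss (GDL).

All operate on plain numpy arrays.  The GDL here is the evaluation-side
mirror of the differentiable loss used in training
(:mod:`tribrats.nn.loss`); the two agree to floating tolerance and are
tested against each other.

GDL = 1 - (2 * sum_l w_l sum g*p + eps) / (sum_l w_l sum (g + p) + eps)
with the per-label weight w_l = 1 / (sum_l g + eps), which down-weights
abundant labels so a tiny tumor class is not swamped by background.
For the binary whole-tumor task there is a single foreground label
(L = 1) and the sums pool over the whole batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_EPSILON = 1e-6


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """The reporting unit of the pipeline: loss / accuracy / DSC."""

    loss: float
    accuracy: float
    dsc: float


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.all(np.isin(np.unique(arr), (0, 1))):
            raise ValueError(f"{name} is not binary")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Voxelwise TP/TN/FP/FN between two binary grids of equal shape."""
    p, g = _check_binary_pair(pred, truth)
    tp = int(np.count_nonzero(p & g))
    tn = int(np.count_nonzero(~p & ~g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp, tn, fp, fn)


def pixel_accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total voxels."""
    if counts.total == 0:
        raise ValueError("empty input: no voxels to score")
    return (counts.tp + counts.tn) / counts.total


def dice_similarity(counts: ConfusionCounts) -> float:
    """DSC = 2TP / (FN + FP + 2TP); 1.0 when both masks are empty."""
    denom = counts.fn + counts.fp + 2 * counts.tp
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def generalized_dice_loss(
    pred_probs, truth, epsilon: float = DEFAULT_EPSILON, label_axis: int | None = None
) -> float:
    """Generalized Dice loss between predicted probabilities and binary truth.

    With ``label_axis=None`` the arrays are treated as one foreground
    label (the binary whole-tumor case).  With an integer ``label_axis``
    that axis of both arrays indexes labels and each label gets its own
    weight 1 / (sum g + eps); sums pool over everything else (per-batch
    weighting).
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if label_axis is None:
        p = p.reshape(1, -1)
        g = g.reshape(1, -1)
    else:
        p = np.moveaxis(p, label_axis, 0).reshape(p.shape[label_axis], -1)
        g = np.moveaxis(g, label_axis, 0).reshape(g.shape[label_axis], -1)
    gsum = g.sum(axis=1)
    psum = p.sum(axis=1)
    inter = (g * p).sum(axis=1)
    w = 1.0 / (gsum + epsilon)
    num = 2.0 * (w * inter).sum() + epsilon
    den = (w * (gsum + psum)).sum() + epsilon
    return float(1.0 - num / den)


def evaluate_pair(
    pred_probs, truth, threshold: float = 0.5, epsilon: float = DEFAULT_EPSILON
) -> EvalReport:
    """Loss/accuracy/DSC for one (probability grid, truth mask) pair."""
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    truth = np.asarray(truth)
    loss = generalized_dice_loss(pred_probs, truth, epsilon)
    hard = (pred_probs >= threshold).astype(np.uint8)
    counts = confusion_counts(hard, truth)
    return EvalReport(loss, pixel_accuracy(counts), dice_similarity(counts))
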
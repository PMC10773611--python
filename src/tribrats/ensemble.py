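"""Per-plane model selection, tri-planar prediction, and majority-vote fusion.

Each anatomical plane gets its own 2D model (for EfficientUNet, the
best of the four three-channel combos by minimum loss).  A case is
predicted slice-wise in all three planes, each plane's probabilities
are reassembled to 3D and binarized at 0.5, and the three masks are
fused voxelwise by the 2-of-3 majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import EvalReport
from .mri_io import CaseRecord, SegmentationMask
from .planes import PLANES, assemble_channel_slices, reassemble_volume


@dataclass
class PlanePrediction:
    plane: str
    combo: object  # ChannelCombo or the four-modality tuple
    probabilities: np.ndarray
    mask: np.ndarray


@dataclass
class VoteResult:
    fused: SegmentationMask
    inputs: tuple[PlanePrediction, PlanePrediction, PlanePrediction]


def binarize_probability(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where probs >= threshold else 0 (note the >= convention)."""
    probs = np.asarray(probs)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(np.uint8)


def majority_vote(masks) -> SegmentationMask:
    """Voxelwise 2-of-3 vote over exactly three binary grids."""
    masks = [np.asarray(m) for m in masks]
    if len(masks) != 3:
        raise ValueError(f"majority vote needs exactly three masks, got {len(masks)}")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("vote masks must share one shape")
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError("vote masks must be binary")
    votes = masks[0].astype(np.uint8) + masks[1] + masks[2]
    return SegmentationMask((votes >= 2).astype(np.uint8))


def select_best_plane_model(reports, metric: str = "loss"):
    """Pick the winning channel combo for one plane from its EvalReports.

    ``reports`` is an ordered mapping combo -> :class:`EvalReport` (or a
    sequence of (combo, report) pairs).  Default selection is minimum
    loss, ties broken by higher DSC, then enumeration order; pass
    ``metric='dsc'`` for max-DSC selection.
    """
    if hasattr(reports, "items"):
        items = list(reports.items())
    else:
        items = list(reports)
    if not items:
        raise ValueError("no candidate reports")
    if metric == "loss":
        key = lambda ir: (ir[1][1].loss, -ir[1][1].dsc, ir[0])
    elif metric == "dsc":
        key = lambda ir: (-ir[1][1].dsc, ir[1][1].loss, ir[0])
    else:
        raise ValueError(f"unknown selection metric {metric!r}")
    best = min(enumerate(items), key=key)
    return best[1][0]


def predict_case_plane(
    model, case: CaseRecord, plane: str, combo, target_inplane=None,
    threshold: float = 0.5, batch_size: int = 16,
) -> PlanePrediction:
    """Slice one plane, predict slice-wise, reassemble to 3D, binarize."""
    inputs, _, stack = assemble_channel_slices(case, combo, plane, target_inplane)
    probs2d = model.predict_proba(inputs, batch_size)[:, 0]
    probs3d = np.clip(reassemble_volume(probs2d, stack), 0.0, 1.0)
    return PlanePrediction(plane, combo, probs3d, binarize_probability(probs3d, threshold))


def predict_case_triplanar(
    case: CaseRecord, models: dict, target_inplane=None, threshold: float = 0.5
) -> VoteResult:
    """Predict a case in all three planes and fuse by majority vote.

    ``models`` maps each plane name to a ``(model, combo)`` pair, where
    ``model`` exposes ``predict_proba`` and ``combo`` is the channel
    tuple that model was trained on.
    """
    if set(models) != set(PLANES):
        raise ValueError(f"need one model per plane {PLANES}, got {tuple(models)}")
    preds = []
    for plane in PLANES:
        model, combo = models[plane]
        preds.append(
            predict_case_plane(model, case, plane, combo, target_inplane, threshold)
        )
    fused = majority_vote([p.mask for p in preds])
    return VoteResult(fused, tuple(preds))
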
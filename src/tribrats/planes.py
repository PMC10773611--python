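"""Tri-planar (2.5D) slicing: 3D volumes <-> axial/coronal/sagittal 2D stacks.

The voxel axes follow the package convention: axis 0 is the sagittal
normal, axis 1 the coronal normal, axis 2 the axial normal.  Slicing a
volume along one of those axes yields a :class:`PlaneStack`; per-slice
predictions are mapped back to 3D by the inverse resize + restack.
Non-square slices (e.g. 128 x 155 coronal slices of a 128 x 128 x 155
volume) are resized per slice to the network's square input and resized
back on reassembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .mri_io import MODALITIES, CaseRecord

PLANES = ("axial", "coronal", "sagittal")
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class ChannelCombo:
    """An ordered triple of distinct modalities fed as network channels."""

    channels: tuple[str, str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(self.channels) != 3 or len(set(self.channels)) != 3:
            raise ValueError("a channel combo is three distinct modalities")
        for m in self.channels:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")

    def __iter__(self):
        return iter(self.channels)

    def __str__(self) -> str:
        return "(" + ", ".join(self.channels) + ")"


#: the four published three-channel combinations evaluated per plane
CHANNEL_COMBOS = (
    ChannelCombo(("FLAIR", "T1ce", "T1")),
    ChannelCombo(("FLAIR", "T1ce", "T2")),
    ChannelCombo(("T2", "T1ce", "T1")),
    ChannelCombo(("FLAIR", "T1", "T2")),
)

#: the full four-modality stack (default U-Net input)
ALL_FOUR = ("FLAIR", "T1ce", "T1", "T2")


@dataclass
class PlaneStack:
    """The ordered 2D slice sequence of one volume along one plane."""

    plane: str
    slices: np.ndarray  # (n_slices, h, w)
    source_shape: tuple[int, int, int]
    slice_axis: int
    per_slice_resize: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.slices.shape[0] != self.source_shape[self.slice_axis]:
            raise ValueError("slice count must equal source_shape[slice_axis]")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def _resize_stack(stack: np.ndarray, target, order: int) -> np.ndarray:
    t0, t1 = int(target[0]), int(target[1])
    if stack.shape[1:] == (t0, t1):
        return stack
    return _sk_resize(
        stack.astype(np.float64),
        (stack.shape[0], t0, t1),
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def extract_plane_stack(
    volume: np.ndarray, plane: str, target_inplane=None, order: int = 1
) -> PlaneStack:
    """Slice a 3D grid along one anatomical plane.

    ``order=1`` (bilinear) suits intensity volumes and probabilities;
    use ``order=0`` for masks.  With ``target_inplane`` every slice is
    resized to that in-plane size; the original geometry is retained for
    :func:`reassemble_volume`.
    """
    if plane not in PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D grid")
    axis = PLANE_AXIS[plane]
    slices = np.moveaxis(volume, axis, 0)
    resize_to = None
    if target_inplane is not None:
        target_inplane = (int(target_inplane[0]), int(target_inplane[1]))
        if slices.shape[1:] != target_inplane:
            slices = _resize_stack(slices, target_inplane, order)
            resize_to = target_inplane
    return PlaneStack(plane, np.ascontiguousarray(slices), volume.shape, axis, resize_to)


def reassemble_volume(per_slice_pred: np.ndarray, stack: PlaneStack) -> np.ndarray:
    """Invert :func:`extract_plane_stack`: resize back and restack to 3D."""
    per_slice_pred = np.asarray(per_slice_pred)
    if per_slice_pred.shape[0] != stack.n_slices:
        raise ValueError(
            f"{per_slice_pred.shape[0]} predictions for {stack.n_slices} slices"
        )
    if stack.per_slice_resize is not None:
        axis = stack.slice_axis
        orig_inplane = tuple(np.delete(np.array(stack.source_shape), axis))
        per_slice_pred = _resize_stack(per_slice_pred, orig_inplane, order=1)
    return np.moveaxis(per_slice_pred, 0, stack.slice_axis)


def assemble_channel_slices(
    case: CaseRecord, combo, plane: str, target_inplane=None
) -> tuple[np.ndarray, np.ndarray, PlaneStack]:
    """Build the multi-channel 2D inputs and aligned mask slices for one plane.

    ``combo`` is a :class:`ChannelCombo` or any ordered sequence of
    modality names (the four-modality stack for the plain U-Net).
    Returns ``(inputs, masks, stack)`` with inputs of shape
    ``(n_slices, n_channels, h, w)`` in exactly the combo's channel
    order, masks of shape ``(n_slices, 1, h, w)`` aligned
    index-for-index, and the geometry stack for inversion.
    """
    channels = tuple(combo)
    for m in channels:
        if m not in case.volumes:
            raise ValueError(f"unknown modality {m!r} in combo")
    stacks = [
        extract_plane_stack(case.volumes[m].voxels, plane, target_inplane, order=1)
        for m in channels
    ]
    mask_stack = extract_plane_stack(
        case.truth.voxels.astype(np.float64), plane, target_inplane, order=0
    )
    inputs = np.stack([s.slices for s in stacks], axis=1).astype(np.float32)
    masks = mask_stack.slices[:, None, :, :].astype(np.float32)
    return inputs, masks, stacks[0]
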
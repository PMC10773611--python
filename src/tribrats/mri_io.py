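"""NIfTI input/output for multimodal brain-MRI cases.

A *case* is one subject: four co-registered MRI modalities (FLAIR, T1ce,
T1, T2) plus a binary whole-tumor mask, all sharing one voxel grid.  On
disk a case is a directory of five NIfTI files named
``<case_id>_<suffix>.nii.gz`` with suffix in ``{flair, t1ce, t1, t2, seg}``,
mirroring common BraTS layouts.

Multi-class label volumes (e.g. BraTS labels 1/2/4) are collapsed to a
binary whole-tumor mask on read: any nonzero label becomes foreground.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("FLAIR", "T1ce", "T1", "T2")

#: on-disk filename suffix for each modality (plus the label file)
_SUFFIX = {"FLAIR": "flair", "T1ce": "t1ce", "T1": "t1", "T2": "t2"}
_SEG_SUFFIX = "seg"


class IncompleteCaseError(FileNotFoundError):
    """A case directory is missing one of the five expected NIfTI files."""


class MisalignedCaseError(ValueError):
    """The five volumes of a case do not share one shape."""


@dataclass
class ModalityVolume:
    """One 3D scalar MRI volume of a known modality.

    Axes follow the package convention: axis 0 is the sagittal normal,
    axis 1 the coronal normal, axis 2 the axial normal; 0-based indexing.
    """

    voxels: np.ndarray
    modality: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegmentationMask:
    """Binary 3D whole-tumor mask (values 0/1)."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask is not binary; found values {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class CaseRecord:
    """One subject: exactly one volume per modality plus the truth mask."""

    case_id: str
    volumes: dict[str, ModalityVolume] = field(default_factory=dict)
    truth: SegmentationMask = None

    def __post_init__(self) -> None:
        if set(self.volumes) != set(MODALITIES):
            raise ValueError(
                f"case {self.case_id!r} needs exactly the modalities {MODALITIES}, "
                f"got {tuple(self.volumes)}"
            )
        shapes = {v.shape for v in self.volumes.values()} | {self.truth.shape}
        if len(shapes) != 1:
            raise MisalignedCaseError(f"case {self.case_id!r}: mixed shapes {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.truth.shape


def binarize_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse a multi-class label grid to binary whole-tumor (nonzero -> 1).

    Idempotent: applying it to an already-binary mask is a no-op.
    """
    return (np.asarray(labels) != 0).astype(np.uint8)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_case(case_dir: str | os.PathLike) -> CaseRecord:
    """Read one case directory into a :class:`CaseRecord`.

    Raises
    ------
    IncompleteCaseError
        if any of the five expected files is missing ("incomplete case").
    MisalignedCaseError
        if the five grids do not share one shape ("misaligned case").
    """
    case_dir = Path(case_dir)
    case_id = case_dir.name

    def _find(suffix: str) -> Path:
        for ext in (".nii.gz", ".nii"):
            p = case_dir / f"{case_id}_{suffix}{ext}"
            if p.exists():
                return p
        raise IncompleteCaseError(
            f"incomplete case {case_id!r}: missing '{case_id}_{suffix}.nii(.gz)'"
        )

    volumes = {}
    for modality, suffix in _SUFFIX.items():
        img = nib.load(_find(suffix))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        volumes[modality] = ModalityVolume(
            np.asarray(img.dataobj, dtype=np.float32), modality, spacing
        )
    seg_img = nib.load(_find(_SEG_SUFFIX))
    truth = SegmentationMask(binarize_labels(np.asarray(seg_img.dataobj)))
    return CaseRecord(case_id, volumes, truth)


def write_case(case: CaseRecord, out_dir: str | os.PathLike) -> list[Path]:
    """Write a case as five NIfTI files in the layout :func:`read_case` expects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for modality, suffix in _SUFFIX.items():
        vol = case.volumes[modality]
        img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol.spacing))
        path = out_dir / f"{case.case_id}_{suffix}.nii.gz"
        nib.save(img, path)
        written.append(path)
    ref = case.volumes["FLAIR"]
    path = out_dir / f"{case.case_id}_{_SEG_SUFFIX}.nii.gz"
    write_mask(case.truth, path, ref)
    written.append(path)
    return written


def write_mask(
    mask: SegmentationMask, path: str | os.PathLike, reference: ModalityVolume
) -> Path:
    """Write a binary mask as uint8 NIfTI in the reference volume's geometry."""
    if mask.shape != reference.shape:
        raise ValueError(f"mask shape {mask.shape} != reference shape {reference.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(reference.spacing))
    nib.save(img, path)
    return path
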
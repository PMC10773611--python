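"""Multimodal MRI phantoms with the contrast structure of glioma imaging.

The generator produces BraTS-like cases at desk scale: an ellipsoidal
"brain" of roughly constant tissue intensity on an exactly-zero
background, one or more spherical tumors whose contrast follows the
clinical pattern per modality (hyperintense on FLAIR/T2, hypointense on
T1, rim-enhancing on T1ce), additive Gaussian noise inside the brain,
and two optional corruption operators used to exercise the
preprocessing stage: a smooth multiplicative bias field and a truncated
("defective") acquisition that zeroes a band of every in-plane slice of
one modality.

Everything is a pure function of its seed, so datasets are exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .mri_io import MODALITIES, CaseRecord, ModalityVolume, SegmentationMask
from .preprocess import BiasField


@dataclass
class ModalityContrast:
    """Mean intensities (arbitrary units) for one modality.

    ``rim`` is only used by rim-enhancing modalities (T1ce): the outer
    30 % shell of each tumor takes the rim intensity, the core the
    ``tumor`` intensity.
    """

    brain: float
    tumor: float
    rim: float | None = None


#: clinical contrast pattern: FLAIR/T2 tumors bright, T1 tumors dark,
#: T1ce bright rim around a core slightly darker than brain.
DEFAULT_CONTRAST: dict[str, ModalityContrast] = {
    "FLAIR": ModalityContrast(brain=100.0, tumor=180.0),
    "T2": ModalityContrast(brain=110.0, tumor=190.0),
    "T1": ModalityContrast(brain=120.0, tumor=70.0),
    "T1ce": ModalityContrast(brain=110.0, tumor=90.0, rim=200.0),
}


@dataclass
class PhantomParams:
    """Geometry, contrast and noise of one phantom case."""

    shape: tuple[int, int, int] = (64, 64, 48)
    brain_axes: tuple[float, float, float] = (28.0, 28.0, 20.0)
    tumor_count: int = 2
    tumor_radius_range: tuple[float, float] = (4.0, 9.0)
    contrast_table: dict[str, ModalityContrast] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tumor_count < 0:
            raise ValueError("tumor_count must be >= 0")
        if self.tumor_radius_range[0] > self.tumor_radius_range[1]:
            raise ValueError("tumor_radius_range must be (lo, hi) with lo <= hi")
        if self.tumor_radius_range[1] >= min(self.brain_axes):
            raise ValueError("tumor radii must fit inside the brain ellipsoid")
        if set(self.contrast_table) != set(MODALITIES):
            raise ValueError(f"contrast_table must cover exactly {MODALITIES}")

    @classmethod
    def for_shape(cls, shape, **kwargs) -> "PhantomParams":
        """Defaults with brain and tumor geometry scaled to a grid size."""
        shape = tuple(int(s) for s in shape)
        m = min(shape)
        return cls(
            shape=shape,
            brain_axes=tuple(0.44 * s for s in shape),
            tumor_radius_range=(max(2.0, 0.08 * m), max(3.0, 0.17 * m)),
            **kwargs,
        )


class PlacementError(RuntimeError):
    """A tumor could not be placed inside the brain ellipsoid."""


def _grid(shape):
    return np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")


def _brain_mask(shape, axes) -> np.ndarray:
    ii, jj, kk = _grid(shape)
    c = [(n - 1) / 2.0 for n in shape]
    r = (
        ((ii - c[0]) / axes[0]) ** 2
        + ((jj - c[1]) / axes[1]) ** 2
        + ((kk - c[2]) / axes[2]) ** 2
    )
    return r <= 1.0


def _place_tumors(params: PhantomParams, rng: np.random.Generator):
    """Sample tumor centers/radii so each sphere sits fully inside the brain."""
    shape, axes = params.shape, params.brain_axes
    c = np.array([(n - 1) / 2.0 for n in shape])
    tumors = []
    for _ in range(params.tumor_count):
        radius = float(rng.uniform(*params.tumor_radius_range))
        for _attempt in range(200):
            u = rng.uniform(-1.0, 1.0, size=3)
            center = c + u * (np.array(axes) - radius - 1.0)
            # inside test in ellipsoid coordinates shrunk by the radius
            shrunk = np.array(axes) - radius
            if np.sum(((center - c) / shrunk) ** 2) <= 1.0:
                tumors.append((center, radius))
                break
        else:
            raise PlacementError(
                f"placement failure: tumor of radius {radius:.1f} does not fit"
            )
    return tumors


def make_phantom_case(params: PhantomParams) -> CaseRecord:
    """Generate one phantom :class:`CaseRecord` deterministically from its seed.

    The background outside the brain ellipsoid is exactly zero; the
    truth mask is the union of the tumor spheres.
    """
    rng = np.random.default_rng(params.seed)
    brain = _brain_mask(params.shape, params.brain_axes)
    tumors = _place_tumors(params, rng)

    ii, jj, kk = _grid(params.shape)
    tumor_mask = np.zeros(params.shape, dtype=bool)
    rim_mask = np.zeros(params.shape, dtype=bool)
    for center, radius in tumors:
        d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
        sphere = d2 <= radius**2
        tumor_mask |= sphere
        rim_mask |= sphere & (d2 > (0.7 * radius) ** 2)
    tumor_mask &= brain
    rim_mask &= brain

    volumes = {}
    for modality in MODALITIES:
        contrast = params.contrast_table[modality]
        vox = np.zeros(params.shape, dtype=np.float32)
        vox[brain] = contrast.brain
        vox[tumor_mask] = contrast.tumor
        if contrast.rim is not None:
            vox[rim_mask] = contrast.rim
        if params.noise_sd > 0:
            noise = rng.normal(0.0, params.noise_sd, size=params.shape)
            vox[brain] += noise[brain].astype(np.float32)
        # keep the brain strictly positive so intensity>0 stays a brain mask
        vox[brain] = np.maximum(vox[brain], 1.0)
        volumes[modality] = ModalityVolume(vox, modality)

    truth = SegmentationMask(tumor_mask.astype(np.uint8))
    return CaseRecord(f"phantom-{params.seed:06d}", volumes, truth)


def inject_defect(case: CaseRecord, modality: str, cut_fraction: float) -> CaseRecord:
    """Zero a contiguous band of every in-plane slice of one modality.

    Emulates a truncated acquisition: ``cut_fraction`` of the first
    in-plane axis is set to zero on every axial slice of the named
    modality; the other modalities and the truth mask are untouched.
    Returns a new case; the input is not modified.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if not 0.0 < cut_fraction < 1.0:
        raise ValueError("cut_fraction must lie strictly between 0 and 1")
    n_cut = int(round(cut_fraction * case.shape[0]))
    volumes = {}
    for name, vol in case.volumes.items():
        vox = vol.voxels.copy()
        if name == modality:
            vox[:n_cut, :, :] = 0.0
        volumes[name] = ModalityVolume(vox, name, vol.spacing)
    return CaseRecord(case.case_id, volumes, SegmentationMask(case.truth.voxels.copy()))


def _random_log_poly(shape, strength, rng) -> np.ndarray:
    """Random degree-2 polynomial over [-1,1]^3 coordinates, coefficients ~N(0, strength^2)."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coeffs = rng.normal(0.0, strength, size=len(terms))
    out = np.zeros(shape, dtype=np.float64)
    for c, t in zip(coeffs, terms):
        out += c * t
    return out


def inject_bias_field(
    volume: ModalityVolume, strength: float, seed: int
) -> tuple[ModalityVolume, BiasField]:
    """Multiply a volume by a smooth positive bias field; return (volume, field).

    The field is the exponential of a random degree-2 polynomial in
    normalized coordinates (hence strictly positive and smooth), scaled
    to mean 1 over the brain mask (voxels > 0).  ``strength`` is the
    standard deviation of the polynomial coefficients; 0 gives the
    identity field.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    field_grid = np.exp(_random_log_poly(volume.shape, strength, np.random.default_rng(seed)))
    fg = volume.voxels > 0
    norm = field_grid[fg].mean() if fg.any() else field_grid.mean()
    field_grid = field_grid / norm
    corrupted = (volume.voxels * field_grid).astype(np.float32)
    return ModalityVolume(corrupted, volume.modality, volume.spacing), BiasField(field_grid)


def make_dataset(
    n_cases: int,
    params: PhantomParams | None = None,
    defect_rate: float = 0.0,
    seed: int = 0,
    cut_fraction: float = 0.4,
) -> list[CaseRecord]:
    """Generate a reproducible list of phantom cases.

    Seeding procedure (stable contract, replayable by callers): a single
    ``np.random.default_rng(seed)`` first draws one per-case seed via
    ``rng.integers(0, 2**31 - 1, size=n_cases)``, then one Bernoulli
    defect draw per case via ``rng.random(n_cases) < defect_rate``, then
    for each defective case one modality index via
    ``rng.integers(0, 4)``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    defective = rng.random(n_cases) < defect_rate
    cases = []
    for i in range(n_cases):
        p = dataclasses.replace(params, seed=int(case_seeds[i]))
        case = make_phantom_case(p)
        if defective[i]:
            modality = MODALITIES[int(rng.integers(0, len(MODALITIES)))]
            case = inject_defect(case, modality, cut_fraction)
        cases.append(case)
    return cases
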
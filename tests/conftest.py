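import numpy as np
import pytest

from tribrats.mri_io import MODALITIES, CaseRecord, ModalityVolume, SegmentationMask
from tribrats.synthetic import PhantomParams, make_phantom_case


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """A small phantom geometry that keeps per-test cost low."""
    return PhantomParams(
        shape=(32, 32, 24),
        brain_axes=(14.0, 14.0, 10.0),
        tumor_count=1,
        tumor_radius_range=(3.0, 5.0),
        noise_sd=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_case(small_params) -> CaseRecord:
    return make_phantom_case(small_params)


@pytest.fixture(scope="session")
def default_case() -> CaseRecord:
    """One default-geometry phantom (64 x 64 x 48)."""
    return make_phantom_case(PhantomParams(seed=11))


def make_case_from_arrays(volumes: dict, mask: np.ndarray, case_id="case") -> CaseRecord:
    vols = {m: ModalityVolume(volumes[m], m) for m in MODALITIES}
    return CaseRecord(case_id, vols, SegmentationMask(mask))
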
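import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tribrats.mri_io import ModalityVolume
from tribrats.preprocess import (
    DIXON_CRITICAL,
    correct_bias_field,
    dixon_q_test,
    filter_defective_cases,
    foreground_area,
    resize_case,
    zscore_normalize,
)
from tribrats.synthetic import inject_bias_field, inject_defect, make_dataset


# ---------------------------------------------------------------------------
# contour area


def test_area_of_empty_slice_is_zero():
    assert foreground_area(np.zeros((8, 8))) == 0.0


def test_area_of_filled_square_matches_shoelace_oracle():
    # polygon through boundary-pixel centres of a 4x4 block is a 3x3 square
    m = np.zeros((10, 10))
    m[2:6, 3:7] = 1
    assert foreground_area(m) == pytest.approx(9.0)


def test_area_uses_largest_component_only():
    m = np.zeros((20, 20))
    m[1:11, 1:6] = 1  # 50 pixels -> contour area 9*4 = 36
    m[15:16, 10:15] = 1  # 5 pixels
    assert foreground_area(m) == pytest.approx(36.0)
    assert foreground_area(m, convention="pixels") == 50.0


def test_degenerate_components_have_zero_area():
    single = np.zeros((5, 5))
    single[2, 2] = 1
    line = np.zeros((5, 5))
    line[2, 1:4] = 1
    assert foreground_area(single) == 0.0
    assert foreground_area(line) == 0.0


# ---------------------------------------------------------------------------
# Dixon's Q


def test_dixon_worked_example():
    r = dixon_q_test([9245.5, 14609, 14617, 14625.5], alpha=0.001)
    assert round(r.q, 4) == 0.9969
    assert r.critical == 0.964
    assert r.is_outlier
    assert r.sorted_values == (9245.5, 14609.0, 14617.0, 14625.5)


def test_dixon_hand_example():
    r = dixon_q_test([10, 90, 95, 100], alpha=0.05)
    assert round(r.q, 4) == 0.8889
    assert r.critical == 0.766
    assert r.is_outlier


def test_dixon_zero_range_contract():
    r = dixon_q_test([5.0, 5.0, 5.0, 5.0], alpha=0.001)
    assert r.q == 0.0 and not r.is_outlier


def test_dixon_rejects_unknown_alpha_and_bad_input():
    with pytest.raises(KeyError, match="critical"):
        dixon_q_test([1, 2, 3, 4], alpha=0.03)
    with pytest.raises(ValueError):
        dixon_q_test([1, 2, 3], alpha=0.05)
    with pytest.raises(ValueError):
        dixon_q_test([1, 2, 3, np.nan], alpha=0.05)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    values=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=4),
    a=st.floats(0.01, 100.0),
    b=st.floats(-1e5, 1e5),
)
def test_dixon_scale_shift_invariance_and_range(values, a, b):
    """Q(a*x + b) = Q(x) for a > 0, and Q always lies in [0, 1]."""
    base = dixon_q_test(values, alpha=0.05)
    assert 0.0 <= base.q <= 1.0
    transformed = dixon_q_test([a * v + b for v in values], alpha=0.05)
    assert transformed.q == pytest.approx(base.q, abs=1e-6)
    # order invariance
    shuffled = dixon_q_test(list(reversed(values)), alpha=0.05)
    assert shuffled.q == base.q


def test_filter_keeps_clean_and_rejects_defective(small_params):
    cases = make_dataset(5, small_params, defect_rate=0.0, seed=21)
    kept, rejected = filter_defective_cases(cases, alpha=0.001)
    assert len(kept) == 5 and rejected == []

    bad = inject_defect(cases[2], "FLAIR", 0.4)
    bad = dataclasses.replace(bad, case_id="defective")
    mixed = cases[:2] + [bad] + cases[3:]
    kept, rejected = filter_defective_cases(mixed, alpha=0.001)
    assert [cid for cid, _ in rejected] == ["defective"]
    assert len(kept) == 4
    assert rejected[0][1].q > rejected[0][1].critical


def test_filter_empty_input():
    assert filter_defective_cases([]) == ([], [])


# ---------------------------------------------------------------------------
# bias correction


def test_bias_free_phantom_is_nearly_unchanged(small_case):
    vol = small_case.volumes["T1"]
    corrected, _ = correct_bias_field(vol)
    fg = vol.voxels > 0
    rel = np.abs(corrected.voxels[fg] - vol.voxels[fg]) / vol.voxels[fg].mean()
    assert np.mean(rel) < 0.01


def test_bias_recovery_and_mean_preservation(small_case):
    vol = small_case.volumes["FLAIR"]
    corrupted, injected = inject_bias_field(vol, 0.3, seed=4)
    corrected, estimated = correct_bias_field(corrupted)
    fg = vol.voxels > 0
    corr = np.corrcoef(injected.field[fg], estimated.field[fg])[0, 1]
    assert corr >= 0.95
    assert corrected.voxels[fg].mean() == pytest.approx(
        corrupted.voxels[fg].mean(), rel=1e-3
    )


def test_bias_correction_requires_foreground():
    empty = ModalityVolume(np.zeros((8, 8, 8), dtype=np.float32), "T1")
    with pytest.raises(ValueError, match="foreground"):
        correct_bias_field(empty)


# ---------------------------------------------------------------------------
# resize and z-score


def test_resize_shapes_and_identity(small_case):
    out = resize_case(small_case, (16, 16))
    assert out.shape == (16, 16, small_case.shape[2])
    assert set(np.unique(out.truth.voxels)) <= {0, 1}
    same = resize_case(small_case, small_case.shape[:2])
    np.testing.assert_array_equal(same.volumes["T1"].voxels, small_case.volumes["T1"].voxels)


def test_resize_preserves_constant_volumes(small_case):
    const = {m: ModalityVolume(np.full(small_case.shape, 3.5, dtype=np.float32), m)
             for m in small_case.volumes}
    case = dataclasses.replace(small_case, volumes=const)
    out = resize_case(case, (20, 20))
    np.testing.assert_allclose(out.volumes["FLAIR"].voxels, 3.5, rtol=1e-6)


def test_zscore_hand_example():
    vox = np.zeros((3, 1, 1), dtype=np.float32)
    vox[:, 0, 0] = [1, 2, 3]
    out, stats = zscore_normalize(ModalityVolume(vox, "T1"))
    assert stats.mu == pytest.approx(2.0)
    assert stats.delta == pytest.approx(0.8165, abs=1e-4)  # population SD
    np.testing.assert_allclose(
        out.voxels[:, 0, 0], [-1.2247, 0.0, 1.2247], atol=1e-4
    )


def test_zscore_constant_foreground_maps_to_zero():
    vox = np.zeros((4, 4, 4), dtype=np.float32)
    vox[1:3, 1:3, 1:3] = 7.0
    out, stats = zscore_normalize(ModalityVolume(vox, "T1"))
    assert stats.delta == 0.0
    assert np.all(out.voxels == 0)


def test_zscore_standardizes_and_is_idempotent(default_case):
    vol = default_case.volumes["T2"]
    out, _ = zscore_normalize(vol)
    fg = vol.voxels != 0
    assert abs(out.voxels[fg].mean()) < 1e-6
    assert abs(out.voxels[fg].std() - 1.0) < 1e-6
    # background untouched
    assert np.all(out.voxels[~fg] == 0)
    again, stats2 = zscore_normalize(out)
    np.testing.assert_allclose(again.voxels, out.voxels, atol=1e-5)
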
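import itertools

import numpy as np
import pytest

from tribrats.ensemble import (
    binarize_probability,
    majority_vote,
    predict_case_triplanar,
    select_best_plane_model,
)
from tribrats.metrics import EvalReport
from tribrats.planes import PLANES, ChannelCombo


def test_binarize_conventions():
    half = np.full((3, 3), 0.5)
    np.testing.assert_array_equal(binarize_probability(half, 0.5), np.ones((3, 3)))
    np.testing.assert_array_equal(binarize_probability(half, 0.0), np.ones((3, 3)))
    np.testing.assert_array_equal(binarize_probability(half, 1.01), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        binarize_probability(np.array([1.5]))


def test_binarize_matches_loop_oracle():
    rng = np.random.default_rng(0)
    probs = rng.random((16, 16))
    out = binarize_probability(probs, 0.5)
    for i in range(16):
        for j in range(16):
            assert out[i, j] == (1 if probs[i, j] >= 0.5 else 0)


def test_majority_vote_exhaustive_truth_table():
    """All 8 voxel vote patterns follow the 2-of-3 rule."""
    patterns = list(itertools.product([0, 1], repeat=3))
    m1 = np.array([p[0] for p in patterns]).reshape(8, 1, 1)
    m2 = np.array([p[1] for p in patterns]).reshape(8, 1, 1)
    m3 = np.array([p[2] for p in patterns]).reshape(8, 1, 1)
    fused = majority_vote([m1, m2, m3]).voxels
    for k, p in enumerate(patterns):
        assert fused[k, 0, 0] == (1 if sum(p) >= 2 else 0)


def test_majority_vote_symmetry_and_unanimity():
    rng = np.random.default_rng(1)
    masks = [(rng.random((6, 6, 6)) < 0.5).astype(np.uint8) for _ in range(3)]
    base = majority_vote(masks).voxels
    for perm in itertools.permutations(masks):
        np.testing.assert_array_equal(majority_vote(list(perm)).voxels, base)
    np.testing.assert_array_equal(majority_vote([masks[0]] * 3).voxels, masks[0])


def test_majority_vote_envelope():
    """The fused mask lies between the AND and the OR of its inputs."""
    rng = np.random.default_rng(2)
    masks = [(rng.random((8, 8, 8)) < 0.4).astype(np.uint8) for _ in range(3)]
    fused = majority_vote(masks).voxels
    land = masks[0] & masks[1] & masks[2]
    lor = masks[0] | masks[1] | masks[2]
    assert np.all(fused >= land) and np.all(fused <= lor)


def test_majority_vote_input_validation():
    m = np.zeros((2, 2, 2), dtype=np.uint8)
    with pytest.raises(ValueError, match="three"):
        majority_vote([m, m])
    with pytest.raises(ValueError, match="shape"):
        majority_vote([m, m, np.zeros((3, 3, 3), dtype=np.uint8)])
    with pytest.raises(ValueError, match="binary"):
        majority_vote([m, m, np.full((2, 2, 2), 2)])


def _published_plane_metrics(plane):
    """Published per-plane EfficientUNet training metrics for each combo."""
    rows = {
        "axial": {
            ("FLAIR", "T1ce", "T1"): (0.0429, 0.9986, 0.9563),
            ("FLAIR", "T1ce", "T2"): (0.0428, 0.9986, 0.9566),
            ("FLAIR", "T1", "T2"): (0.0447, 0.9985, 0.9542),
            ("T2", "T1ce", "T1"): (0.0531, 0.9983, 0.9448),
        },
        "coronal": {
            ("FLAIR", "T1ce", "T1"): (0.0435, 0.9986, 0.9558),
            ("FLAIR", "T1ce", "T2"): (0.0440, 0.9986, 0.9549),
            ("FLAIR", "T1", "T2"): (0.0442, 0.9986, 0.9547),
            ("T2", "T1ce", "T1"): (0.0516, 0.9983, 0.9473),
        },
        "sagittal": {
            ("FLAIR", "T1ce", "T1"): (0.0429, 0.9986, 0.9565),
            ("FLAIR", "T1ce", "T2"): (0.0433, 0.9986, 0.9560),
            ("FLAIR", "T1", "T2"): (0.0427, 0.9986, 0.9562),
            ("T2", "T1ce", "T1"): (0.0508, 0.9984, 0.9475),
        },
    }
    return {
        ChannelCombo(c): EvalReport(loss, acc, dsc)
        for c, (loss, acc, dsc) in rows[plane].items()
    }


def test_plane_selection_reproduces_stated_optima():
    """Argmin-loss per plane picks the combos the study states as optimal."""
    assert select_best_plane_model(_published_plane_metrics("axial")).channels == ("FLAIR", "T1ce", "T2")
    assert select_best_plane_model(_published_plane_metrics("coronal")).channels == ("FLAIR", "T1ce", "T1")
    assert select_best_plane_model(_published_plane_metrics("sagittal")).channels == ("FLAIR", "T1", "T2")


def test_plane_selection_edge_cases():
    single = {ChannelCombo(("FLAIR", "T1ce", "T1")): EvalReport(0.5, 0.9, 0.5)}
    assert select_best_plane_model(single).channels == ("FLAIR", "T1ce", "T1")
    with pytest.raises(ValueError):
        select_best_plane_model({})
    # loss tie broken by higher DSC
    tied = {
        ChannelCombo(("FLAIR", "T1ce", "T1")): EvalReport(0.1, 0.9, 0.7),
        ChannelCombo(("FLAIR", "T1ce", "T2")): EvalReport(0.1, 0.9, 0.8),
    }
    assert select_best_plane_model(tied).channels == ("FLAIR", "T1ce", "T2")
    # max-DSC mode
    assert select_best_plane_model(tied, metric="dsc").channels == ("FLAIR", "T1ce", "T2")


class _OracleModel:
    """Fake slice model returning a fixed probability for truth pixels."""

    def __init__(self, mode):
        self.mode = mode  # "truth" or "zero"

    def predict_proba(self, batch, batch_size=16):
        if self.mode == "zero":
            return np.zeros((batch.shape[0], 1) + batch.shape[2:], dtype=np.float32)
        # channel 0 carries the truth mask in this test harness
        return batch[:, :1].astype(np.float32)


def _mask_case(small_case):
    """A case whose FLAIR channel equals the truth mask (oracle harness)."""
    import dataclasses

    from tribrats.mri_io import ModalityVolume

    vols = {
        m: ModalityVolume(small_case.truth.voxels.astype(np.float32), m)
        for m in small_case.volumes
    }
    return dataclasses.replace(small_case, volumes=vols)


@pytest.mark.parametrize(
    "modes,expect_truth",
    [
        (("truth", "truth", "truth"), True),
        (("truth", "truth", "zero"), True),
        (("truth", "zero", "zero"), False),
    ],
)
def test_triplanar_two_of_three_with_oracle_models(small_case, modes, expect_truth):
    case = _mask_case(small_case)
    combo = ChannelCombo(("FLAIR", "T1ce", "T2"))
    models = {p: (_OracleModel(m), combo) for p, m in zip(PLANES, modes)}
    vote = predict_case_triplanar(case, models)
    expected = case.truth.voxels if expect_truth else np.zeros_like(case.truth.voxels)
    np.testing.assert_array_equal(vote.fused.voxels, expected)
    assert len(vote.inputs) == 3
    for pred in vote.inputs:
        assert pred.probabilities.shape == case.shape
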
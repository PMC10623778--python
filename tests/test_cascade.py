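"""Cascade post-processing and false-positive reduction contracts."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from hepaseg.cascade import (
    CascadeSpec,
    apply_liver_mask,
    postprocess_liver,
    reduce_false_positives,
    run_cascade,
)
from hepaseg.containers import MultisequenceVolume, ProbabilityMap, SegmentationMask
from hepaseg.unetpp import NetworkSpec, build_network

SPEC = CascadeSpec()


def _prob_map(fg: np.ndarray, spacing=(5.0, 1.0, 1.0)) -> ProbabilityMap:
    fg = np.asarray(fg, dtype=np.float64)
    return ProbabilityMap(np.stack([1 - fg, fg]), spacing)


# ------------------------------------------------------------ liver stage


def test_largest_component_survives():
    fg = np.zeros((6, 20, 20))
    fg[1:3, 2:12, 2:7] = 0.9  # 100-voxel block (per slice 50, two slices)
    fg[4, 15:16, 15:20] = 0.9  # 5-voxel sliver
    out = postprocess_liver(_prob_map(fg), CascadeSpec(closing_radius_vox=0))
    assert out.labels[1, 5, 5] == 1
    assert out.labels[4, 15, 16] == 0
    _, n = ndimage.label(out.labels, structure=np.ones((3, 3, 3)))
    assert n == 1


def test_closing_fills_interior_hole():
    fg = np.zeros((5, 16, 16))
    fg[1:4, 3:13, 3:13] = 1.0
    fg[2, 7, 7] = 0.0  # one-voxel void, smaller than the closing element
    out = postprocess_liver(_prob_map(fg), SPEC)
    assert out.labels[2, 7, 7] == 1


def test_closing_leaves_solid_interior_unchanged():
    """On a hole-free blob, closing must not alter the voxel set away from
    the border (oracle: direct comparison against the binarized input)."""
    fg = np.zeros((7, 24, 24))
    zz, yy, xx = np.mgrid[:7, :24, :24]
    ball = ((zz - 3) * 3.0) ** 2 + (yy - 12.0) ** 2 + (xx - 12.0) ** 2 <= 81
    fg[ball] = 0.95
    out = postprocess_liver(_prob_map(fg), SPEC)
    binary = fg >= 0.5
    interior = ndimage.binary_erosion(binary, np.ones((3, 5, 5)))
    assert np.array_equal(out.labels.astype(bool) & interior, interior)
    assert np.all(out.labels[binary])  # extensive: nothing removed


def test_empty_probability_yields_flagged_empty_mask():
    with pytest.warns(UserWarning):
        out = postprocess_liver(_prob_map(np.zeros((4, 8, 8))), SPEC)
    assert out.labels.sum() == 0


def test_postprocess_component_count_at_most_one(rng):
    for _ in range(10):
        fg = (rng.random((6, 16, 16)) > 0.7).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = postprocess_liver(_prob_map(fg), SPEC)
        _, n = ndimage.label(out.labels, structure=np.ones((3, 3, 3)))
        assert n <= 1


# ------------------------------------------------------------ conditioning


def test_full_mask_passthrough(rng):
    vol = MultisequenceVolume(rng.random((2, 4, 16, 16)), (5.0, 1.0, 1.0))
    liver = SegmentationMask(np.ones((4, 16, 16), np.int16), (5.0, 1.0, 1.0))
    s2 = apply_liver_mask(vol, liver, margin_vox=0)
    assert np.array_equal(s2.image[:2], vol.channels)
    assert np.all(s2.image[2] == 1.0)


def test_empty_mask_skip_path(rng):
    vol = MultisequenceVolume(rng.random((2, 4, 16, 16)), (5.0, 1.0, 1.0))
    liver = SegmentationMask(np.zeros((4, 16, 16), np.int16), (5.0, 1.0, 1.0))
    with pytest.warns(UserWarning):
        s2 = apply_liver_mask(vol, liver)
    assert s2.empty


def test_masking_zeroes_outside_dilated_mask(rng):
    vol = MultisequenceVolume(rng.random((2, 6, 24, 24)) + 1.0, (5.0, 1.0, 1.0))
    labels = np.zeros((6, 24, 24), np.int16)
    labels[2:4, 8:16, 8:16] = 1
    liver = SegmentationMask(labels, (5.0, 1.0, 1.0))
    s2 = apply_liver_mask(vol, liver, margin_vox=2)
    outside = ~s2.dilated_liver[s2.crop_slices]
    assert np.all(s2.image[0][outside] == 0)
    assert np.all(s2.image[1][outside] == 0)
    # third channel is the un-dilated mask
    assert np.array_equal(s2.image[2] > 0, labels[s2.crop_slices] > 0)


# ------------------------------------------------------- FP reduction


def test_mean_probability_threshold_rule():
    mask = np.zeros((4, 12, 12), bool)
    mask[1, 2:4, 2:4] = True  # component A
    mask[2, 8:10, 8:10] = True  # component B
    fg = np.zeros((4, 12, 12))
    fg[1, 2:4, 2:4] = 0.9
    fg[2, 8:10, 8:10] = 0.3
    out, comps = reduce_false_positives(_prob_map(fg), mask, SPEC)
    assert sorted(c.kept for c in comps) == [False, True]
    assert out.labels.sum() == 4
    assert out.labels[1, 2, 2] == 1


def test_tau_zero_is_identity(rng):
    mask = rng.random((5, 10, 10)) > 0.7
    fg = rng.random((5, 10, 10))
    spec = CascadeSpec(fp_mean_prob_threshold=0.0)
    out, _ = reduce_false_positives(_prob_map(fg), mask, spec)
    assert np.array_equal(out.labels.astype(bool), mask)


def test_survivor_count_monotone_in_tau_against_oracle(rng):
    """Sweep tau over random fields; per-component means are recomputed with
    an independent per-component averaging oracle."""
    struct = np.ones((3, 3, 3))
    for _ in range(20):
        mask = rng.random((5, 12, 12)) > 0.75
        fg = rng.random((5, 12, 12))
        prev = np.inf
        labels, n = ndimage.label(mask, structure=struct)
        oracle_means = [fg[labels == k].mean() for k in range(1, n + 1)]
        for tau in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = CascadeSpec(fp_mean_prob_threshold=tau)
            _, comps = reduce_false_positives(_prob_map(fg), mask, spec)
            means = sorted(c.mean_probability for c in comps)
            assert means == pytest.approx(sorted(oracle_means))
            kept = sum(c.kept for c in comps)
            assert kept == sum(m >= tau for m in oracle_means)
            assert kept <= prev
            prev = kept


def test_volume_floor_removes_small_components():
    mask = np.zeros((3, 10, 10), bool)
    mask[1, 1:5, 1:5] = True  # 16 voxels * 5 mm3
    mask[1, 8, 8] = True  # 1 voxel
    fg = np.full((3, 10, 10), 0.9)
    spec = CascadeSpec(min_lesion_volume_mm3=10.0)
    out, comps = reduce_false_positives(_prob_map(fg), mask, spec)
    assert sum(c.kept for c in comps) == 1
    assert out.labels.sum() == 16


def test_fp_reduction_is_idempotent(rng):
    mask = rng.random((5, 12, 12)) > 0.7
    fg = rng.random((5, 12, 12))
    once, _ = reduce_false_positives(_prob_map(fg), mask, SPEC)
    twice, _ = reduce_false_positives(_prob_map(fg), once.labels, SPEC)
    assert np.array_equal(once.labels, twice.labels)


# ----------------------------------------------------------- full cascade


@pytest.fixture(scope="module")
def untrained_nets():
    s1 = build_network(NetworkSpec(depth=2, base_filters=2), seed=0)
    s2 = build_network(NetworkSpec(depth=2, base_filters=2, in_channels=3), seed=1)
    return s1, s2


def test_cascade_containment_invariant(untrained_nets, rng):
    """Even with arbitrary (untrained) networks, predicted tumor voxels can
    never leave the dilated liver mask."""
    s1, s2 = untrained_nets
    vol = MultisequenceVolume(rng.random((2, 6, 24, 24)), (5.0, 1.0, 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_cascade(s1, s2, vol, SPEC)
    tumor = res.tumor.labels.astype(bool)
    if res.dilated_liver is not None:
        assert not np.any(tumor & ~res.dilated_liver)
    assert res.tumor.shape == vol.shape
    assert res.liver.shape == vol.shape


def test_cascade_empty_liver_skips_stage2(untrained_nets):
    s1, s2 = untrained_nets
    # zero input drives stage-1 softmax to whatever it likes; force the
    # empty path by a liver threshold of 1.0
    vol = MultisequenceVolume(np.zeros((2, 4, 16, 16)), (5.0, 1.0, 1.0))
    spec = CascadeSpec(liver_prob_threshold=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_cascade(s1, s2, vol, spec)
    assert res.tumor.labels.sum() == 0
    assert res.lesions == []
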
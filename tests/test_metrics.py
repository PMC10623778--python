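"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from hepaseg.containers import SegmentationMask
from hepaseg.metrics import (
    afpr,
    concordance_correlation,
    dice,
    evaluate_cohort,
    match_lesions,
)

STRUCT26 = np.ones((3, 3, 3), dtype=bool)


# -------------------------------------------------------------------- dice


def test_dice_trivial_cases():
    a = np.zeros((4, 4, 4), bool)
    a[1:3, 1:3, 1:3] = True
    assert dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[3, 3, 3] = True
    assert dice(a, b) == 0.0
    assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0  # both-empty


def test_dice_half_overlap():
    a = np.zeros((2, 2, 2), bool)
    b = np.zeros((2, 2, 2), bool)
    a.ravel()[:4] = True
    b.ravel()[2:6] = True
    assert dice(a, b) == 0.5  # |A|=4, |B|=4, |A n B|=2


def test_dice_symmetry_and_grid_check(rng):
    a = rng.random((3, 4, 4)) > 0.5
    b = rng.random((3, 4, 4)) > 0.5
    assert dice(a, b) == dice(b, a)
    with pytest.raises(ValueError):
        dice(a, np.zeros((2, 2, 2)))


# ------------------------------------------------------------ lesion match


def brute_force_match(pred, truth):
    """Independent oracle: explicit pairwise overlap of labelled components."""
    lt, nt = ndimage.label(truth, structure=STRUCT26)
    lp, npred = ndimage.label(pred, structure=STRUCT26)
    overlap = np.zeros((nt, npred), int)
    for i in range(1, nt + 1):
        for j in range(1, npred + 1):
            overlap[i - 1, j - 1] = int(np.sum((lt == i) & (lp == j)))
    detected = [bool(overlap[i].sum()) for i in range(nt)]
    fp = sum(1 for j in range(npred) if overlap[:, j].sum() == 0)
    dscs = []
    for i in range(nt):
        js = [j for j in range(npred) if overlap[i, j] > 0]
        if not js:
            dscs.append(0.0)
            continue
        union = np.isin(lp, [j + 1 for j in js])
        t = lt == i + 1
        dscs.append(2 * np.sum(union & t) / (union.sum() + t.sum()))
    return nt, npred, detected, fp, dscs


def test_match_extra_predictions_are_false_positives():
    truth = np.zeros((3, 10, 10), bool)
    truth[1, 2:4, 2:4] = True
    pred = truth.copy()
    pred[0, 7:9, 7:9] = True
    pred[2, 0:2, 5:7] = True
    m = match_lesions(pred, truth)
    assert (m.fp_count, m.sensitivity) == (2, 1.0)


def test_match_empty_prediction():
    truth = np.zeros((3, 8, 8), bool)
    truth[0, 1:3, 1:3] = True
    truth[2, 5:7, 5:7] = True
    m = match_lesions(np.zeros_like(truth), truth)
    assert m.sensitivity == 0.0
    assert m.fp_count == 0
    assert m.per_lesion_dice == [0.0, 0.0]


def test_match_randomized_against_brute_force(rng):
    """100 random small masks against the exhaustive pairwise-overlap oracle."""
    for _ in range(100):
        shape = tuple(rng.integers(3, 7, size=3))
        pred = rng.random(shape) > 0.6
        truth = rng.random(shape) > 0.6
        m = match_lesions(pred, truth)
        nt, npred, detected, fp, dscs = brute_force_match(pred, truth)
        assert m.n_true == nt and m.n_pred == npred
        assert m.detected == detected
        assert m.fp_count == fp
        assert m.per_lesion_dice == pytest.approx(dscs)


def test_min_overlap_fraction_stricter_matching():
    truth = np.zeros((1, 8, 8), bool)
    truth[0, 0:2, 0:2] = True
    pred = np.zeros_like(truth)
    pred[0, 1:6, 1:6] = True  # overlaps 1 voxel of a 25-voxel component
    loose = match_lesions(pred, truth)
    strict = match_lesions(pred, truth, min_overlap_fraction=0.5)
    assert loose.fp_count == 0 and loose.sensitivity == 1.0
    assert strict.fp_count == 1 and strict.sensitivity == 0.0


# -------------------------------------------------------------------- afpr


def test_afpr_arithmetic():
    assert afpr([2, 0, 1]) == 1.0
    assert afpr([0, 0, 0]) == 0.0
    counts = [3, 1, 0, 2, 2, 0, 1, 4, 2]  # 9 cases, hand-summed mean 15/9
    assert afpr(counts) == pytest.approx(15 / 9)
    assert afpr(reversed(counts)) == afpr(counts)  # order invariance
    with pytest.raises(ValueError):
        afpr([])


# --------------------------------------------------------------------- CCC


def test_ccc_perfect_agreement():
    x = np.array([1.0, 2.0, 5.0, 7.0])
    assert concordance_correlation(x, x) == pytest.approx(1.0)


def test_ccc_perfect_antisymmetry():
    x = np.array([-2.0, -1.0, 1.0, 2.0])  # zero mean
    assert concordance_correlation(x, -x) == pytest.approx(-1.0)


def test_ccc_hand_computed_moments():
    # population moments evaluated by hand for these eight numbers
    x = [1, 2, 3, 4]
    y = [1.1, 2.1, 2.9, 4.2]
    assert concordance_correlation(x, y) == pytest.approx(0.9931170108161257)


def test_ccc_log_transform_guards_zero_volumes():
    x = [0.0, 100.0, 1000.0]
    y = [0.0, 90.0, 1100.0]
    val = concordance_correlation(x, y, log_transform=True)
    ref = concordance_correlation(np.log(np.array(x) + 1), np.log(np.array(y) + 1))
    assert val == pytest.approx(ref)


def test_ccc_degenerate_signals():
    with pytest.raises(ValueError):
        concordance_correlation([2.0, 2.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        concordance_correlation([1.0], [1.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=3, max_size=12),
    st.integers(0, 2**31 - 1),
)
def test_ccc_bounded_by_pearson(xs, seed):
    """Lin's inequality |CCC| <= |r| on random non-degenerate vectors."""
    x = np.asarray(xs)
    y = x * 0.5 + np.random.default_rng(seed).normal(size=len(x))
    if np.var(x) < 1e-9 or np.var(y) < 1e-9:
        return
    ccc = concordance_correlation(x, y)
    r = np.corrcoef(x, y)[0, 1]
    assert abs(ccc) <= abs(r) + 1e-12


# ------------------------------------------------------------------ cohort


def _mask(labels):
    return SegmentationMask(labels.astype(np.int16), (5.0, 1.0, 1.0))


def test_perfect_prediction_report():
    labels = np.zeros((4, 12, 12), np.int16)
    labels[1:3, 2:10, 2:10] = 1
    labels[2, 4:6, 4:6] = 2
    case = {
        "case_id": "c0",
        "truth": _mask(labels),
        "pred_liver": labels >= 1,
        "pred_tumor": labels == 2,
    }
    rep = evaluate_cohort([case])
    assert rep.summary["mean_liver_dsc"] == 1.0
    assert rep.summary["mean_tumor_dsc_case"] == 1.0
    assert rep.summary["afpr"] == 0.0
    assert rep.summary["sensitivity"] == 1.0


def test_missed_lesion_scores_zero_in_per_lesion_table():
    labels = np.zeros((4, 12, 12), np.int16)
    labels[1:3, 2:10, 2:10] = 1
    labels[1, 3:5, 3:5] = 2  # detected lesion
    labels[2, 7:8, 7:8] = 2  # sub-resolution lesion, missed below
    pred_tumor = labels == 2
    pred_tumor[2, 7, 7] = False
    rep = evaluate_cohort(
        [
            {
                "case_id": "c0",
                "truth": _mask(labels),
                "pred_liver": labels >= 1,
                "pred_tumor": pred_tumor,
            }
        ]
    )
    dscs = sorted(rep.per_lesion["dsc"])
    assert dscs[0] == 0.0 and dscs[1] == 1.0
    assert rep.summary["sensitivity"] == 0.5


def test_missing_prediction_reported_not_dropped():
    labels = np.zeros((2, 8, 8), np.int16)
    labels[0, 2:4, 2:4] = 1
    rep = evaluate_cohort(
        [{"case_id": "gone", "truth": _mask(labels), "pred_liver": None, "pred_tumor": None}]
    )
    assert rep.summary["missing_predictions"] == ["gone"]
    assert rep.summary["n_cases"] == 0


def test_summary_consistent_with_per_case_table(rng):
    """Random multi-case cohort: summary means must equal recomputation from
    the per-case and per-lesion tables."""
    cases = []
    for i in range(5):
        labels = np.zeros((4, 10, 10), np.int16)
        labels[1:3, 1:9, 1:9] = 1
        for _ in range(rng.integers(1, 3)):
            z, y, x = rng.integers(1, 3), rng.integers(2, 7), rng.integers(2, 7)
            labels[z, y : y + 2, x : x + 2] = 2
        pred_t = (labels == 2) & (rng.random(labels.shape) > 0.3)
        if rng.random() < 0.5:
            pred_t[3, 0:2, 0:2] = True  # an off-lesion FP component
        cases.append(
            {
                "case_id": f"c{i}",
                "truth": _mask(labels),
                "pred_liver": labels >= 1,
                "pred_tumor": pred_t,
            }
        )
    rep = evaluate_cohort(cases)
    assert rep.summary["afpr"] == pytest.approx(rep.per_case["fp_count"].mean())
    assert rep.summary["mean_tumor_dsc_case"] == pytest.approx(
        rep.per_case["tumor_dsc"].mean()
    )
    if len(rep.per_lesion):
        assert rep.summary["mean_tumor_dsc_lesion"] == pytest.approx(
            rep.per_lesion["dsc"].mean()
        )
        assert rep.summary["sensitivity"] == pytest.approx(
            rep.per_lesion["detected"].mean()
        )


def test_report_export(tmp_path):
    labels = np.zeros((2, 8, 8), np.int16)
    labels[0, 2:6, 2:6] = 1
    labels[0, 3, 3] = 2
    rep = evaluate_cohort(
        [
            {
                "case_id": "c0",
                "truth": _mask(labels),
                "pred_liver": labels >= 1,
                "pred_tumor": labels == 2,
            }
        ]
    )
    rep.to_files(tmp_path)
    assert (tmp_path / "per_case.csv").exists()
    assert (tmp_path / "per_lesion.csv").exists()
    assert (tmp_path / "summary.json").exists()
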
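"""Segmentation and lesion-detection evaluation.

Per-case quantities: liver and tumor Dice similarity coefficients (DSC),
lesion detection sensitivity, and the number of false-positive lesion
components under the zero-overlap rule — a predicted connected component
that overlaps no true lesion by even one voxel is a false positive.
Cohort summaries add the average false-positivity rate (AFPR, mean FP
count per case), the lesion-based mean DSC (a missed lesion scores exactly
0), and Lin's concordance correlation coefficient (CCC) between log
true and predicted lesion volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """DSC = 2|A n B| / (|A| + |B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (sa + sb)


@dataclass
class LesionMatches:
    """Outcome of lesion-level matching for one case."""

    n_true: int
    n_pred: int
    detected: list[bool]  # per true lesion
    fp_count: int
    per_lesion_dice: list[float]  # per true lesion; 0 when missed
    true_volumes_mm3: list[float]
    matched_pred_volumes_mm3: list[float]  # union of matched preds, 0 if missed

    @property
    def sensitivity(self) -> float:
        if self.n_true == 0:
            return 1.0
        return sum(self.detected) / self.n_true


def match_lesions(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    connectivity: int = 26,
    spacing_mm=(1.0, 1.0, 1.0),
    min_overlap_fraction: float = 0.0,
) -> LesionMatches:
    """Match predicted to true lesion components by voxel overlap.

    A true lesion counts as detected when any predicted component overlaps
    it (many-to-one allowed); its DSC is computed against the union of all
    predicted components that touch it.  ``min_overlap_fraction`` optionally
    demands that a predicted component devote at least that fraction of its
    voxels to true lesions before it counts as matched (0 = the literal
    one-voxel rule).
    """
    pred = np.asarray(pred_mask) > 0
    truth = np.asarray(truth_mask) > 0
    if pred.shape != truth.shape:
        raise ValueError("grid mismatch")
    st = _structure(connectivity)
    lt, n_true = ndimage.label(truth, structure=st)
    lp, n_pred = ndimage.label(pred, structure=st)

    # overlap matrix via a joint histogram of the two label volumes
    overlap = np.zeros((n_true + 1, n_pred + 1), dtype=np.int64)
    np.add.at(overlap, (lt.ravel(), lp.ravel()), 1)

    pred_sizes = overlap.sum(axis=0)[1:]
    pred_overlap_true = overlap[1:, 1:].sum(axis=0)
    matched_pred = np.zeros(n_pred, dtype=bool)
    for j in range(n_pred):
        frac = pred_overlap_true[j] / pred_sizes[j] if pred_sizes[j] else 0.0
        matched_pred[j] = pred_overlap_true[j] > 0 and frac >= min_overlap_fraction

    voxvol = float(np.prod(spacing_mm))
    detected, dscs, tvols, pvols = [], [], [], []
    for i in range(1, n_true + 1):
        touching = [
            j for j in range(1, n_pred + 1) if overlap[i, j] > 0 and matched_pred[j - 1]
        ]
        detected.append(bool(touching))
        t_size = int(overlap[i, :].sum())
        tvols.append(t_size * voxvol)
        if touching:
            union = np.isin(lp, touching)
            inter = sum(int(overlap[i, j]) for j in touching)
            u_size = int(union.sum())
            dscs.append(2.0 * inter / (t_size + u_size))
            pvols.append(u_size * voxvol)
        else:
            dscs.append(0.0)
            pvols.append(0.0)

    fp_count = int(n_pred - matched_pred.sum())
    return LesionMatches(
        n_true=n_true,
        n_pred=n_pred,
        detected=detected,
        fp_count=fp_count,
        per_lesion_dice=dscs,
        true_volumes_mm3=tvols,
        matched_pred_volumes_mm3=pvols,
    )


def afpr(fp_counts) -> float:
    """Average false-positivity rate: mean false-positive lesions per case."""
    fp_counts = list(fp_counts)
    if not fp_counts:
        raise ValueError("afpr needs at least one case")
    return float(np.mean(fp_counts))


def concordance_correlation(
    x, y, log_transform: bool = False, log_offset: float = 1.0
) -> float:
    """Lin's CCC = 2 cov(x,y) / (var x + var y + (mean x - mean y)^2).

    Population (1/n) moments, per Lin's original definition.  With
    ``log_transform`` the natural log of ``value + log_offset`` is taken
    first — the convention used for comparing lesion volumes, where the
    offset guards zero volumes of missed lesions.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1D with n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if log_transform:
        if np.any(x + log_offset <= 0) or np.any(y + log_offset <= 0):
            raise ValueError("log transform needs value + offset > 0")
        x = np.log(x + log_offset)
        y = np.log(y + log_offset)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero variance and equal means")
    return float(2.0 * cov / denom)


@dataclass
class EvalReport:
    """Per-case and per-lesion tables plus cohort summary statistics."""

    per_case: pd.DataFrame
    per_lesion: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_files(self, out_dir) -> None:
        from pathlib import Path
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(out_dir / "per_case.csv", index=False)
        self.per_lesion.to_csv(out_dir / "per_lesion.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)


def evaluate_cohort(cases, connectivity: int = 26) -> EvalReport:
    """Evaluate a cohort of segmented cases.

    ``cases`` is an iterable of dicts with keys ``case_id``, ``truth``
    (:class:`~hepaseg.containers.SegmentationMask` with labels 0/1/2),
    ``pred_liver`` and ``pred_tumor`` (binary masks or ``None`` when a
    prediction is missing, which is reported rather than dropped).
    Both the case-based and the lesion-based aggregations are filled.
    """
    case_rows, lesion_rows = [], []
    fp_counts, case_tumor_dscs, missing = [], [], []
    for case in cases:
        cid = case["case_id"]
        truth = case["truth"]
        if case.get("pred_liver") is None or case.get("pred_tumor") is None:
            missing.append(cid)
            continue
        t_liver = np.asarray(truth.labels) >= 1  # tumors live inside the liver
        t_tumor = np.asarray(truth.labels) == 2
        p_liver = np.asarray(
            getattr(case["pred_liver"], "labels", case["pred_liver"])
        ) > 0
        p_tumor = np.asarray(
            getattr(case["pred_tumor"], "labels", case["pred_tumor"])
        ) > 0
        liver_dsc = dice(p_liver, t_liver)
        tumor_dsc = dice(p_tumor, t_tumor)
        m = match_lesions(
            p_tumor, t_tumor, connectivity=connectivity, spacing_mm=truth.spacing_mm
        )
        case_rows.append(
            {
                "case_id": cid,
                "liver_dsc": liver_dsc,
                "tumor_dsc": tumor_dsc,
                "n_true_lesions": m.n_true,
                "n_pred_lesions": m.n_pred,
                "n_detected": int(sum(m.detected)),
                "fp_count": m.fp_count,
                "sensitivity": m.sensitivity,
            }
        )
        fp_counts.append(m.fp_count)
        case_tumor_dscs.append(tumor_dsc)
        for i in range(m.n_true):
            lesion_rows.append(
                {
                    "case_id": cid,
                    "lesion": i + 1,
                    "detected": m.detected[i],
                    "dsc": m.per_lesion_dice[i],
                    "true_volume_mm3": m.true_volumes_mm3[i],
                    "pred_volume_mm3": m.matched_pred_volumes_mm3[i],
                }
            )

    per_case = pd.DataFrame(case_rows)
    per_lesion = pd.DataFrame(lesion_rows)
    summary: dict = {"n_cases": len(case_rows), "missing_predictions": missing}
    if case_rows:
        summary.update(
            mean_liver_dsc=float(per_case["liver_dsc"].mean()),
            mean_tumor_dsc_case=float(per_case["tumor_dsc"].mean()),
            afpr=afpr(fp_counts),
            sensitivity=(
                float(per_case["n_detected"].sum() / per_case["n_true_lesions"].sum())
                if per_case["n_true_lesions"].sum()
                else 1.0
            ),
        )
    if len(per_lesion):
        summary["mean_tumor_dsc_lesion"] = float(per_lesion["dsc"].mean())
        tv = per_lesion["true_volume_mm3"].to_numpy()
        pv = per_lesion["pred_volume_mm3"].to_numpy()
        if len(tv) >= 2:
            try:
                summary["volume_ccc_log"] = concordance_correlation(
                    tv, pv, log_transform=True
                )
            except ValueError:
                summary["volume_ccc_log"] = float("nan")
    return EvalReport(per_case=per_case, per_lesion=per_lesion, summary=summary)
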
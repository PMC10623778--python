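"""NIfTI I/O and the preprocessing chain.

The pipeline standardizes every case the same way the clinical protocol
implies: resample to 1.0 x 1.0 mm in-plane with 5.0 mm slices, rigidly
co-register the T2 channel onto the arterial grid, strip the pure-black
background frame, clip intensities at the 99.8% quantile of the nonzero
voxels and rescale to [0, 1].

Axis convention: arrays are (z, y, x); the NIfTI affine encodes spacing and
is the source of truth on disk.  Crop intervals are half-open, 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .containers import MultisequenceVolume, SegmentationMask

# ------------------------------------------------------------------- spec


@dataclass(frozen=True)
class PreprocessSpec:
    """Targets of the standardization step."""

    target_spacing_mm: tuple[float, float, float] = (5.0, 1.0, 1.0)
    clip_quantile: float = 0.998
    background_value: float = 0.0

    def validate(self) -> None:
        if not 0 < self.clip_quantile <= 1:
            raise ValueError("clip_quantile must be in (0, 1]")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")


# ------------------------------------------------------------------ NIfTI


def save_nifti(array: np.ndarray, spacing_mm, path, origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write a (z,y,x) array as NIfTI with spacing encoded in the affine."""
    affine = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    affine[:3, 3] = [origin_mm[2], origin_mm[1], origin_mm[0]]
    data = np.asarray(array).transpose(2, 1, 0)  # store (x, y, z)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a NIfTI file; returns (array (z,y,x), spacing_mm, origin_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    origin = (float(t[2]), float(t[1]), float(t[0]))
    return data, spacing, origin


def save_case(case, out_dir) -> None:
    """Write a phantom/clinical case as the on-disk triplet + lesion JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cid = case.case_id
    sp = case.volume.spacing_mm
    save_nifti(case.volume.arterial, sp, out_dir / f"{cid}_art.nii.gz")
    save_nifti(case.volume.t2, sp, out_dir / f"{cid}_t2.nii.gz")
    save_nifti(case.truth.labels.astype(np.int16), sp, out_dir / f"{cid}_mask.nii.gz")
    with open(out_dir / f"{cid}_lesions.json", "w") as fh:
        json.dump(
            [
                {"center_vox": list(c), "radius_mm": r, "volume_mm3": v}
                for c, r, v in case.lesion_catalog
            ],
            fh,
            indent=2,
        )


def load_case(out_dir, case_id):
    """Inverse of :func:`save_case`; returns (volume, truth, lesion_catalog)."""
    out_dir = Path(out_dir)
    art, sp, origin = load_nifti(out_dir / f"{case_id}_art.nii.gz")
    t2, _, _ = load_nifti(out_dir / f"{case_id}_t2.nii.gz")
    mask, _, _ = load_nifti(out_dir / f"{case_id}_mask.nii.gz")
    vol = MultisequenceVolume(np.stack([art, t2]), sp, origin)
    truth = SegmentationMask(np.rint(mask).astype(np.int16), sp, origin)
    catalog = []
    lesion_path = out_dir / f"{case_id}_lesions.json"
    if lesion_path.exists():
        with open(lesion_path) as fh:
            catalog = [
                (tuple(e["center_vox"]), e["radius_mm"], e["volume_mm3"])
                for e in json.load(fh)
            ]
    return vol, truth, catalog


# --------------------------------------------------------------- resample


def _resample_array(arr, spacing, target, order):
    out_shape = tuple(
        int(round(n * s / t)) for n, s, t in zip(arr.shape, spacing, target)
    )
    if out_shape == arr.shape and np.allclose(spacing, target):
        return arr.copy()
    if any(n == 0 for n in out_shape):
        raise ValueError("resampling would produce a degenerate (zero-size) grid")
    zoom = [no / ni for no, ni in zip(out_shape, arr.shape)]
    return ndimage.zoom(arr, zoom, order=order, grid_mode=True, mode="nearest")


def resample_volume(
    vol: MultisequenceVolume,
    target_spacing_mm,
    mask: SegmentationMask | None = None,
):
    """Resample to a new voxel size; linear for intensities, nearest for labels.

    The output grid size is ``round(n * s / s_target)`` per axis, which
    preserves the physical extent to within one output voxel.
    """
    target = tuple(float(t) for t in target_spacing_mm)
    channels = np.stack(
        [_resample_array(ch, vol.spacing_mm, target, order=1) for ch in vol.channels]
    )
    out = MultisequenceVolume(channels, target, vol.origin_mm, meta=dict(vol.meta))
    if mask is None:
        return out
    labels = _resample_array(mask.labels, mask.spacing_mm, target, order=0)
    return out, SegmentationMask(labels, target, mask.origin_mm)


# ------------------------------------------------------------ registration


@dataclass
class RigidTransform:
    """6-DOF result: Euler angles (rad) and translation in mm, (z,y,x) order."""

    rotation_rad: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    converged: bool


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing_mm,
) -> tuple[RigidTransform, np.ndarray]:
    """Rigidly align ``moving`` onto ``fixed`` (same grid, (z,y,x) arrays).

    The optimizer is delegated to SimpleITK (Mattes mutual information +
    regular-step gradient descent, standard for multisequence MR).  The
    returned translation is the offset that maps fixed-grid points into the
    moving image, in (z,y,x) millimetres; the second return value is the
    moving channel resampled onto the fixed grid.  Non-convergence (e.g.
    structureless inputs) is flagged, never raised.
    """
    sp_xyz = (float(spacing_mm[2]), float(spacing_mm[1]), float(spacing_mm[0]))
    f = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float64))
    m = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float64))
    f.SetSpacing(sp_xyz)
    m.SetSpacing(sp_xyz)

    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.5, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=200,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(init, inPlace=False)
    converged = True
    try:
        tf = reg.Execute(f, m)
    except RuntimeError:
        tf = init
        converged = False

    resampled = sitk.Resample(m, f, tf, sitk.sitkLinear, 0.0)
    out = sitk.GetArrayFromImage(resampled)

    # sanity check: registration of structureless data gives no real
    # alignment; flag via correlation of the overlap
    fi, mo = fixed.ravel(), out.ravel()
    sel = (np.abs(fi) + np.abs(mo)) > 0
    if sel.sum() > 16 and np.std(fi[sel]) > 0 and np.std(mo[sel]) > 0:
        r = np.corrcoef(fi[sel], mo[sel])[0, 1]
        if not np.isfinite(r) or abs(r) < 0.3:
            converged = False
    else:
        converged = False

    params = np.asarray(tf.GetParameters())
    rot_xyz, t_xyz = params[:3], params[3:6]
    result = RigidTransform(
        rotation_rad=(float(rot_xyz[2]), float(rot_xyz[1]), float(rot_xyz[0])),
        translation_mm=(float(t_xyz[2]), float(t_xyz[1]), float(t_xyz[0])),
        converged=converged,
    )
    return result, out


# ----------------------------------------------------------- crop / clip


@dataclass(frozen=True)
class CropOffsets:
    """Half-open crop window and the original shape, for exact paste-back."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]
    original_shape: tuple[int, int, int]

    @property
    def slices(self):
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))


def crop_background(
    vol: MultisequenceVolume,
    *masks: SegmentationMask,
    background_value: float = 0.0,
    margin_inplane: int = 2,
):
    """Strip the pure-black background frame around the tissue.

    The crop window is the tight bounding box of voxels where any channel
    exceeds ``background_value``, expanded by a 2-voxel in-plane margin and
    clamped to the grid; z is cropped tightly (empty frames carry no
    anatomy).  Returns ``(cropped volume, [cropped masks...], offsets)``.
    """
    body = np.any(vol.channels > background_value, axis=0)
    if not body.any():
        raise ValueError("volume is entirely background")
    idx = np.argwhere(body)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    margins = (0, margin_inplane, margin_inplane)
    start = tuple(int(max(0, a - m)) for a, m in zip(lo, margins))
    stop = tuple(
        int(min(n, b + m)) for b, m, n in zip(hi, margins, vol.shape)
    )
    off = CropOffsets(start, stop, tuple(vol.shape))
    sl = off.slices
    out_vol = MultisequenceVolume(
        vol.channels[(slice(None),) + sl],
        vol.spacing_mm,
        tuple(o + s * sp for o, s, sp in zip(vol.origin_mm, start, vol.spacing_mm)),
        meta=dict(vol.meta),
    )
    out_masks = [
        SegmentationMask(msk.labels[sl], msk.spacing_mm, out_vol.origin_mm)
        for msk in masks
    ]
    if masks:
        return out_vol, out_masks, off
    return out_vol, off


def uncrop(array: np.ndarray, offsets: CropOffsets, fill=0) -> np.ndarray:
    """Paste a cropped (label or probability) array back onto the full grid."""
    out = np.full(offsets.original_shape, fill, dtype=np.asarray(array).dtype)
    out[offsets.slices] = array
    return out


def clip_intensities(
    channel: np.ndarray,
    clip_quantile: float = 0.998,
    background_value: float = 0.0,
) -> np.ndarray:
    """Clip at the upper-quantile of non-background voxels, rescale to [0,1].

    The quantile is the nearest-rank (sorted-order) value over voxels above
    ``background_value``: the zero background would otherwise drag the
    quantile down.  A constant channel degenerates to all zeros, with a
    warning.  Idempotent on nonnegative images with a zero background.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("empty channel")
    vals = channel[channel > background_value]
    if vals.size == 0:
        warnings.warn("channel has no voxels above background; returning zeros")
        return np.zeros_like(channel)
    cut = float(np.quantile(vals, clip_quantile, method="inverted_cdf"))
    clipped = np.minimum(channel, cut)
    lo = clipped.min()
    span = cut - lo
    if span <= 0:
        warnings.warn("constant channel after clipping; returning zeros")
        return np.zeros_like(channel)
    return (clipped - lo) / span
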
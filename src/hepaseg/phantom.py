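"""Synthetic dual-sequence liver MR phantoms with ground truth.

Each phantom emulates the geometry the downstream cascade has to cope with:
one large smooth liver, up to three small spherical tumors strictly inside
it, bright tubular vessels that overlap the tumor intensity range in the
arterial channel (the classic false-positive confounder), one or two
background "organs", additive Gaussian noise, and an optional rigid
misregistration of the T2 channel.

Intensity model (arbitrary units, plateaus before noise):

===========  =========  =====
tissue       arterial    T2
===========  =========  =====
background     0.00      0.00
organ          0.30      0.35
liver          0.45      0.40
vessel         0.80      0.50
tumor          0.85      0.62
===========  =========  =====

Tumors are hyperintense in the arterial phase and intermediate in T2;
vessels sit just below the tumor plateau in the arterial phase so that an
intensity-driven segmenter will produce vessel false positives for the
probability-threshold reduction stage to remove.  Noise is additive
Gaussian per channel — an adequate approximation to Rician MR noise at
moderate SNR, and a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import LIVER, TUMOR, MultisequenceVolume, SegmentationMask

# Tissue plateau intensities per (tissue, channel).
PLATEAUS = {
    "background": (0.00, 0.00),
    "organ": (0.30, 0.35),
    "liver": (0.45, 0.40),
    "vessel": (0.80, 0.50),
    "tumor": (0.85, 0.62),
}

#: Reference contrast amplitude: brightest plateau above background.
CONTRAST_AMPLITUDE = 0.85

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class PhantomError(RuntimeError):
    """Raised when a phantom spec cannot be satisfied (e.g. liver too small)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``noise_sigma`` is expressed as a fraction of the tissue-contrast
    amplitude (the brightest plateau above background), so 0.05 means a
    noise standard deviation of 5% of the liver-to-tumor intensity scale.
    """

    grid_shape: tuple[int, int, int] = (24, 96, 96)
    spacing_mm: tuple[float, float, float] = (5.0, 1.0, 1.0)
    n_tumors: int = 2
    tumor_radius_range_mm: tuple[float, float] = (4.0, 12.0)
    n_vessels: int = 2
    noise_sigma: float = 0.05
    misregistration_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 8 for g in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not 0 <= self.n_tumors <= 3:
            raise ValueError("n_tumors must be in [0, 3]")
        rmin, rmax = self.tumor_radius_range_mm
        if rmin <= 0 or rmax < rmin:
            raise ValueError("tumor radii must be positive with min <= max")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.misregistration_mm < 0:
            raise ValueError("misregistration_mm must be >= 0")


@dataclass
class PhantomCase:
    """A generated case: images, ground-truth labels and the lesion catalog."""

    volume: MultisequenceVolume
    truth: SegmentationMask
    #: one entry per tumor: (center voxel (z,y,x), radius_mm, volume_mm3)
    lesion_catalog: list[tuple[tuple[int, int, int], float, float]]
    spec: PhantomSpec = field(default=None)  # type: ignore[assignment]
    case_id: str = "case_0000"


def _ellipsoid_mask(shape, center_vox, semi_axes_vox, rotation=None, wobble=None):
    """Boolean mask of a (rotated, optionally perturbed) ellipsoid.

    ``wobble`` is a smooth zero-mean field added to the implicit radius,
    giving the organ a gently irregular boundary.
    """
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = np.stack([g - c for g, c in zip(grids, center_vox)])
    if rotation is not None:
        flat = coords.reshape(3, -1)
        coords = (rotation @ flat).reshape(coords.shape)
    u = coords / np.asarray(semi_axes_vox).reshape(3, 1, 1, 1)
    r = np.sqrt((u**2).sum(axis=0))
    thr = 1.0 if wobble is None else 1.0 + wobble
    return r <= thr


def _inplane_rotation(rng: np.random.Generator) -> np.ndarray:
    """Random rotation about the z (slice) axis; slices stay axial."""
    a = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _smooth_field(shape, rng, sigma_vox, amplitude):
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma_vox)
    peak = np.abs(f).max()
    if peak < 1e-12:
        return np.zeros(shape)
    return f * (amplitude / peak)


def _make_liver(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Single-component liver occupying 15-40% of the grid, smooth boundary."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    for _ in range(20):
        # semi-axis fractions tuned so the analytic volume fraction
        # 4/3*pi*fz*fy*fx lands inside (0.15, 0.26) before perturbation
        fz = rng.uniform(0.32, 0.38)
        fy = rng.uniform(0.34, 0.40)
        fx = rng.uniform(0.34, 0.40)
        center = shape / 2 + rng.uniform(-0.03, 0.03, size=3) * shape
        wobble = _smooth_field(spec.grid_shape, rng, sigma_vox=(2, 8, 8), amplitude=0.08)
        mask = _ellipsoid_mask(
            spec.grid_shape,
            center,
            semi_axes_vox=(fz * shape[0], fy * shape[1], fx * shape[2]),
            rotation=_inplane_rotation(rng),
            wobble=wobble,
        )
        lab, n = ndimage.label(mask, structure=_STRUCT_26)
        if n == 0:
            continue
        if n > 1:  # keep largest piece should the wobble pinch something off
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
        frac = mask.mean()
        if 0.15 <= frac <= 0.40:
            return mask
    raise PhantomError("could not generate a liver within the volume-fraction band")


def _voxelize_sphere(shape, center_vox, radius_mm, spacing, subdiv=3):
    """Partial-volume sphere voxelization: a voxel belongs to the sphere if
    at least half of it (estimated on a subdiv^3 sub-grid) lies inside.
    Center sampling alone underestimates small-lesion volume badly at 5 mm
    slices; the 50% coverage rule keeps voxel-counted volume close to
    4/3 pi r^3 down to radii of a few millimetres."""
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(center_vox, dtype=float)
    lo = np.maximum(np.floor(c - radius_mm / sp - 1).astype(int), 0)
    hi = np.minimum(np.ceil(c + radius_mm / sp + 2).astype(int), shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    axes = [np.arange(a, b, dtype=float) for a, b in zip(lo, hi)]
    sub = (np.arange(subdiv) + 0.5) / subdiv - 0.5
    frac = 0.0
    for dz in sub:
        for dy in sub:
            for dx in sub:
                zz, yy, xx = np.meshgrid(
                    axes[0] + dz, axes[1] + dy, axes[2] + dx, indexing="ij"
                )
                d2 = (
                    ((zz - c[0]) * sp[0]) ** 2
                    + ((yy - c[1]) * sp[1]) ** 2
                    + ((xx - c[2]) * sp[2]) ** 2
                )
                frac = frac + (d2 <= radius_mm**2)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = frac >= (subdiv**3) / 2.0
    return mask


def _place_tumors(spec, rng, liver, spacing):
    """Spherical tumors strictly inside the liver, pairwise separated."""
    depth_mm = ndimage.distance_transform_edt(liver, sampling=spacing)
    catalog: list[tuple[tuple[int, int, int], float, float]] = []
    tumor_mask = np.zeros(liver.shape, dtype=bool)
    centers_mm: list[np.ndarray] = []
    radii: list[float] = []
    sp = np.asarray(spacing)
    rmin, rmax = spec.tumor_radius_range_mm
    for _ in range(spec.n_tumors):
        placed = False
        for _try in range(60):
            # anneal the radius toward the minimum when space gets tight
            hi = max(rmin, rmax - (rmax - rmin) * _try / 30.0)
            r = rng.uniform(rmin, hi)
            # strictly inside: at least one voxel of liver beyond the sphere
            candidates = np.argwhere(depth_mm > r + max(spacing))
            if candidates.size == 0:
                continue
            if centers_mm:
                # necessary condition (disjoint continuous spheres) to
                # prune candidates; voxel adjacency is verified below
                cand_mm = candidates * sp
                ok = np.ones(len(candidates), dtype=bool)
                for pc, pr in zip(centers_mm, radii):
                    ok &= np.linalg.norm(cand_mm - pc, axis=1) >= r + pr + 1.0
                candidates = candidates[ok]
                if candidates.size == 0:
                    continue
            c = candidates[rng.integers(len(candidates))]
            c_mm = c * sp
            sphere = _voxelize_sphere(liver.shape, c, r, spacing)
            sphere &= liver
            if not sphere.any():
                continue
            if tumor_mask.any() and (
                ndimage.binary_dilation(sphere, structure=_STRUCT_26) & tumor_mask
            ).any():
                continue  # would 26-touch an existing lesion
            tumor_mask |= sphere
            centers_mm.append(c_mm)
            radii.append(r)
            catalog.append(
                (tuple(int(v) for v in c), float(r), float(4 / 3 * np.pi * r**3))
            )
            placed = True
            break
        if not placed:
            raise PhantomError(
                "tumor placement failed: liver too small for requested radius"
            )
    return tumor_mask, catalog


def _make_vessels(spec, rng, liver, tumor_mask, spacing):
    """Curved bright tubes inside the liver, kept clear of tumors."""
    vessels = np.zeros(liver.shape, dtype=bool)
    interior = np.argwhere(liver)
    if interior.size == 0 or spec.n_vessels == 0:
        return vessels
    sp = np.asarray(spacing)
    grids = np.meshgrid(*[np.arange(n) for n in liver.shape], indexing="ij")
    # tumors plus a 2 mm clearance stay vessel-free so lesion components
    # remain intensity-distinct
    keep_out = ndimage.binary_dilation(
        tumor_mask, iterations=1, structure=_STRUCT_26
    )
    for _ in range(spec.n_vessels):
        p0, p1 = interior[rng.integers(len(interior), size=2)]
        mid = (p0 + p1) / 2 + rng.uniform(-0.15, 0.15, size=3) * np.asarray(
            liver.shape
        )
        radius = rng.uniform(1.0, 3.0)  # mm
        tube = np.zeros(liver.shape, dtype=bool)
        for t in np.linspace(0, 1, 64):
            pt = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * mid + t**2 * p1
            d2 = sum(((g - ci) * si) ** 2 for g, ci, si in zip(grids, pt, sp))
            tube |= d2 <= radius**2
        vessels |= tube & liver & ~keep_out
    return vessels


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case deterministically from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(g) for g in spec.grid_shape)
    spacing = spec.spacing_mm

    liver = _make_liver(spec, rng)
    tumor_mask, catalog = _place_tumors(spec, rng, liver, spacing)
    vessels = _make_vessels(spec, rng, liver, tumor_mask, spacing)

    # one or two extra-hepatic "organs" so background is not uniformly empty
    organs = np.zeros(shape, dtype=bool)
    outside = ~ndimage.binary_dilation(liver, iterations=3)
    for _ in range(rng.integers(1, 3)):
        cand = np.argwhere(outside)
        if cand.size == 0:
            break
        c = cand[rng.integers(len(cand))]
        semi = rng.uniform(0.06, 0.12, size=3) * np.asarray(shape)
        organs |= _ellipsoid_mask(shape, c, semi) & outside

    labels = np.zeros(shape, dtype=np.int16)
    labels[liver] = LIVER
    labels[tumor_mask] = TUMOR  # tumors are inside the liver by construction

    channels = np.zeros((2,) + shape)
    for ch in range(2):
        img = np.zeros(shape)
        img[organs] = PLATEAUS["organ"][ch]
        img[liver] = PLATEAUS["liver"][ch]
        img[vessels] = PLATEAUS["vessel"][ch]
        img[tumor_mask] = PLATEAUS["tumor"][ch]
        channels[ch] = img

    meta = {"seed": spec.seed}
    if spec.misregistration_mm > 0:
        # rigid misregistration reduced to a random translation of the T2
        # channel (rotations at this scale are indistinguishable on a phantom)
        offset_mm = rng.uniform(
            -spec.misregistration_mm, spec.misregistration_mm, size=3
        )
        offset_vox = offset_mm / np.asarray(spacing)
        channels[1] = ndimage.shift(channels[1], offset_vox, order=1, mode="constant")
        meta["t2_offset_mm"] = [float(v) for v in offset_mm]

    if spec.noise_sigma > 0:
        channels = channels + rng.normal(
            0.0, spec.noise_sigma * CONTRAST_AMPLITUDE, size=channels.shape
        )

    vol = MultisequenceVolume(channels, spacing, meta=meta)
    truth = SegmentationMask(labels, spacing)
    return PhantomCase(volume=vol, truth=truth, lesion_catalog=catalog, spec=spec)


def split_sizes(n_cases: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n_cases`` into ``ratios``."""
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    exact = [n_cases * r for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n_cases - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - sizes[i], reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def generate_cohort(
    n_cases: int,
    spec_template: PhantomSpec = PhantomSpec(),
    split_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> tuple[list[PhantomCase], list[PhantomCase], list[PhantomCase]]:
    """Generate ``n_cases`` phantoms and partition them train/val/test.

    Case seeds are spawned from ``spec_template.seed`` so the whole cohort
    is reproducible from one integer; membership of the three splits is a
    seeded permutation, disjoint and exhaustive, default ratio 8:1:1.
    """
    sizes = split_sizes(n_cases, split_ratio)
    n_nonempty = sum(1 for r in split_ratio if r > 0)
    if n_cases < n_nonempty:
        raise ValueError(
            f"n_cases={n_cases} cannot populate {n_nonempty} nonempty splits"
        )
    ss = np.random.SeedSequence(spec_template.seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_cases)]
    cases = []
    for i, seed in enumerate(case_seeds):
        spec_i = PhantomSpec(
            **{**spec_template.__dict__, "seed": seed}
        )
        case = generate_phantom(spec_i)
        case.case_id = f"case_{i:04d}"
        cases.append(case)
    perm = np.random.default_rng(spec_template.seed).permutation(n_cases)
    bounds = np.cumsum([0] + sizes)
    splits = tuple(
        [cases[j] for j in perm[bounds[k] : bounds[k + 1]]] for k in range(3)
    )
    return splits
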
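# Methods

## Problem and approach

`hepaseg` implements automated segmentation of the liver and of
hepatocellular-carcinoma lesions from dual-sequence abdominal MR
(contrast-enhanced arterial phase + T2-weighted), as a two-stage cascade of
2D UNet++ networks:

1. **Stage 1 (liver).** Axial slices of the two co-registered channels are
   segmented liver-vs-rest. Per-slice probabilities are stacked into a 3D
   map, binarized, reduced to the single largest 26-connected component, and
   smoothed by an anisotropy-aware morphological closing.
2. **Stage 2 (tumor).** The stage-1 liver mask conditions the input:
   intensities outside the (in-plane-dilated) mask are zeroed, the binary
   mask is appended as a third channel, and the volume is cropped to the
   liver bounding box. A second UNet++ segments tumor-vs-rest inside this
   field of view.
3. **False-positive reduction.** Connected tumor components are audited by
   their mean tumor-class probability (from the network's final softmax):
   components with mean below a threshold τ, or with volume below an
   optional floor, are deleted. This targets the dominant failure mode of
   intensity-driven tumor detection in arterial-phase MR — bright hepatic
   vessels segmented as lesions.

The cascade structurally guarantees that predicted tumor voxels lie inside
the dilated liver mask; the lesion audit (volume, mean probability,
kept/rejected) is always returned so τ can be calibrated per application.

## Network

UNet++ is an encoder–decoder with nested, dense skip pathways: conv nodes
X(i, j) for i + j ≤ L − 1 on L resolution levels, where X(i, 0) is a plain
encoder chain (2× max-pool) and X(i, j>0) consumes the 2×-upsampled
X(i+1, j−1) concatenated with all of X(i, 0..j−1). Each node is two
3×3 conv + batch-norm + ReLU stages; channel width doubles per level from
`base_filters`. Upsampling is bilinear followed by a 1×1 projection —
chosen over transposed convolution to avoid checkerboard artifacts.
Deep supervision (a head per top-row node, softmax-averaged at inference)
is available but off by default. Each stage is a binary segmenter
(two-class softmax); the cascade structure, not a 3-class head, separates
liver from tumor. Only the 2D variant is implemented; slices are processed
independently and superimposed along z.

The networks run on a compact numpy backend written for this package:
im2col convolutions, a tape-based reverse-mode autodiff engine, batch
normalization, 2×2 max-pooling, bilinear upsampling and Adam with
decoupled weight decay. The backend is exact (gradients are verified
against central finite differences network-wide in the test suite) and
fast enough that the full study profile below trains in minutes on one
CPU core.

## Preprocessing

* **Resampling** to (5.0, 1.0, 1.0) mm (z, y, x): linear interpolation for
  intensities, nearest-neighbour for labels (labels are never invented).
  Output grid size is `round(n·s/s_target)` per axis, preserving physical
  extent to within one output voxel.
* **Rigid registration** of T2 onto the arterial grid (the arterial channel
  defines the grid because tumor contrast lives there): Mattes mutual
  information + regular-step gradient descent, delegated to SimpleITK.
  Non-convergence (e.g. structureless input) is flagged on the returned
  transform, never raised; the flag is driven by the correlation of the
  aligned overlap (|r| < 0.3 ⇒ not converged).
* **Background cropping**: tight bounding box of voxels above the
  background value, +2 voxels of in-plane margin, with offsets recorded so
  predictions paste back voxel-exactly.
* **Intensity clipping** at the 99.8% nearest-rank quantile of voxels above
  background (including the zero frame would drag the quantile down), then
  min–max rescaling to [0, 1]. Per-volume, not per-cohort — an assumption,
  flagged here. The operation is idempotent on nonnegative images with a
  zero background, which is the operating regime of MR magnitude images.

## Training recipe

Per-stage 2D training on axial slices: random crop 224×224 (stage 1) and
128×128 (stage 2) at full scale — the test/study profile uses 64×64 —
with the augmentation menu applied identically to images (linear) and
labels (nearest): scaling 0.8–1.2, rotation ±180°, horizontal/vertical
flips, smooth elastic deformation (max 4-voxel displacement, Gaussian
σ = 8 — the magnitude is a mild default exposed in config), additive
Gaussian noise. Loss is cross-entropy + soft Dice on the foreground class
(smoothing ε = 1), equally weighted; optimizer Adam at lr 0.001 with a
decoupled L2 coefficient of 0.0001 applied to convolution weights only
(placement of the regularizer is a design choice). Slices containing
foreground are sampled with probability 0.8 (uniform otherwise) and crops
are centered on a foreground pixel with probability 0.8, so organ- and
lesion-bearing crops dominate. Epochs and batch size default to 60/8 at
full scale and 5/4 in the study profile; the study profile runs 45
optimization steps per epoch (about two passes over the tumor-bearing
slice pool) — the tumor stage sees only a handful of foreground slices
per case and needs the extra steps to converge reliably within 5 epochs.

With rare foreground, the loss surface has a well-known local optimum —
predict background everywhere with diffuse low foreground probability —
and a small network occasionally draws an initialization that falls into
it (controlled experiments showed the trap depends only on the
initialization, not on the sample stream). The study profile therefore
uses deterministic multi-start: each stage probes three candidate
initializations (seeds spawned from the stage seed) for one epoch and
continues with the one reaching the lowest training loss. Selection is by
training loss only; the probes add roughly half an epoch of compute per
candidate. When validation cases are given,
the best-on-validation snapshot (parameters + batch-norm statistics) is
restored at the end. Stage 2 trains on inputs conditioned by the
*ground-truth* liver mask; at inference the cascade substitutes its own
stage-1 prediction. Training is fully deterministic for a fixed seed on
one CPU thread.

## Thresholds and numerical choices

* Liver binarization 0.5; closing element: in-plane radius 2 voxels,
  1 along z (ellipsoidal), matching the 1×1×5 mm anisotropy. The closing
  result is explicitly unioned with its input (scipy clips at borders) and
  the largest component re-asserted, so the output has ≤ 1 component by
  construction.
* Tumor binarization 0.3, τ = 0.5. The binarization cutoff must sit
  *below* τ: every voxel of a component binarized at cutoff c has
  probability ≥ c, so the component mean is ≥ c and any τ ≤ c would reject
  nothing. With the (0.3, 0.5) pair, confidently segmented lesions
  (component means typically ≥ 0.7) survive while diffuse vessel responses
  (means near the binarization floor) are deleted. τ is the single most
  application-sensitive dial and is exposed everywhere, including the
  per-component audit.
* Component connectivity 26 (8 in-plane + across-slice), configurable to 6.
* Dice convention: both-empty masks score 1.0 (perfect agreement on
  absence) — flagged in reports since clinical cohorts rarely hit it.
* Lesion matching uses the literal zero-overlap rule: one shared voxel
  matches; a predicted component overlapping no true lesion is a false
  positive. Many-to-one matching is allowed, and a true lesion's DSC is
  computed against the union of all components touching it. A stricter
  minimum-overlap fraction is available.
* Lin's CCC uses population (1/n) moments; the volume comparison is done
  on log(volume + 1) mm³, the +1 guarding missed lesions of volume 0.

## Synthetic phantoms

The phantom generator stands in for clinical data and defines the study
conditions. Each case is a two-channel anisotropic volume (default
24×96×96 at (5, 1, 1) mm; the study profile uses 16×72×72) containing:

* a **liver**: a randomly oriented (in-plane) ellipsoid with a smooth
  low-frequency boundary perturbation, occupying 15–40% of the grid,
  always a single 26-connected component;
* up to three **tumors**: spheres of radius 4–12 mm (study profile 4–9 mm,
  emulating a cohort with ~2.2 cm mean diameter and ≤ 3 lesions per
  patient), strictly inside the liver, pairwise non-adjacent, hyperintense
  in the arterial channel and intermediate in T2. Voxelization uses a 50%
  partial-volume coverage rule (3³ subsamples) so voxel-counted volumes
  track 4/3·π·r³ whenever the radius spans ≥ 2 voxels along every axis;
  below that, slice quantization dominates and no binary mask can encode
  the volume accurately;
* 1–3 mm-radius curved **vessels** (quadratic Bézier tubes) inside the
  liver, labeled as liver but nearly as bright as tumor in the arterial
  channel (0.80 vs 0.85) — deliberate confounders for the FP-reduction
  stage;
* one or two extra-hepatic **organ** blobs so the background is not empty;
* additive Gaussian noise per channel (σ expressed as a fraction of the
  tissue-contrast amplitude; default 5%) — an approximation to Rician MR
  noise valid at moderate SNR;
* optionally, a random rigid **misregistration** of the T2 channel
  (reduced to a translation; rotations at this scale are indistinguishable
  on a phantom), recorded in the metadata as ground truth for
  registration tests.

All randomness flows through one seeded generator; identical spec + seed
is bit-identical. Cohorts derive per-case seeds from a single seed
sequence and are partitioned 8:1:1 (largest-remainder apportionment) by a
seeded permutation.

What the phantoms do **not** emulate: anatomical shape variability, bias
fields, k-space/motion artifacts, heterogeneous lesion texture, unclear
lesion boundaries, inter-observer annotation noise. Passing the phantom
study therefore demonstrates that the pipeline's machinery — cascade,
conditioning, post-processing, FP reduction, metrics — is implemented
correctly and can be trained, not that clinical-grade accuracy would be
reached on real MR; on real data the tumor-stage problem is far harder
than intensity thresholding.

## Study profile and evaluation

The end-to-end study (`hepaseg.experiment`, also driven by
`scripts/acceptance.py`) generates 44 phantoms (30 train / 4 validation /
10 test) at 16×72×72, trains both stages with depth-3, 8-filter networks
and 64×64 crops for 5 epochs, runs cascaded inference on the held-out
cases, and reports: mean liver and tumor DSC (case-based), lesion-based
mean DSC, detection sensitivity, AFPR at τ = 0.5 and τ = 0 (same
probability fields), and the CCC of log lesion volumes. These sizes were
chosen so the whole study runs in a few minutes on a single CPU core
while every stage still has nontrivial work; they are the package's
desk-scale study conditions, not a claim about clinical scale.

## Known limitations

* 2D only; no use of through-plane context beyond component analysis.
* The numpy backend is CPU-bound and float64; it is not intended for
  clinical-resolution training.
* Per-volume (not cohort-level) intensity normalization.
* τ has no universally correct value; the default 0.5 (with binarization
  0.3) is calibrated to the phantom contrast model and must be re-examined
  on any real dataset via the lesion audit.
* Registration quality is only sanity-checked by overlap correlation; a
  pathological local optimum with high correlation would not be flagged.
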
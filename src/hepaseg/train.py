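"""Training recipe: augmentation, CE + Dice loss, Adam.

Stage 1 learns liver-vs-rest from dual-sequence axial slices; stage 2
learns tumor-vs-rest from liver-masked three-channel inputs.  The loss is
an equally weighted sum of pixel cross-entropy and soft Dice on the
foreground class (smoothing eps = 1), optimized with Adam at learning rate
1e-3 and a decoupled L2 coefficient of 1e-4 on convolution weights.

The augmentation menu: random scaling (0.8-1.2), rotation (+/-180 deg),
horizontal/vertical flips, smooth elastic deformation, additive noise and
random cropping.  Geometric transforms are applied identically to the
image channels (linear interpolation) and the label (nearest neighbour, so
labels are never invented).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .unetpp import UNetPlusPlus

# --------------------------------------------------------------- losses


def dice_loss(prob: np.ndarray, label: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - (2 sum(p y) + eps) / (sum p + sum y + eps)."""
    prob = np.asarray(prob, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if prob.shape != label.shape:
        raise ValueError(f"shape mismatch {prob.shape} vs {label.shape}")
    num = 2.0 * (prob * label).sum() + eps
    den = prob.sum() + label.sum() + eps
    return float(1.0 - num / den)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean pixel cross-entropy; ``probs`` (N,C,H,W), ``labels`` (N,H,W) int."""
    p_true = np.take_along_axis(probs, labels[:, None], axis=1)[:, 0]
    return float(-np.log(np.clip(p_true, eps, 1.0)).mean())


def combined_loss(
    probs: np.ndarray, labels: np.ndarray, weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """w_ce * CE + w_dice * foreground soft Dice, on class probabilities."""
    w_ce, w_dice = weights
    return w_ce * cross_entropy(probs, labels) + w_dice * dice_loss(
        probs[:, 1], labels > 0
    )


def combined_loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
    eps: float = 1.0,
):
    """Loss and its analytic gradient with respect to the logits.

    The softmax, cross-entropy and Dice terms are fused so the gradient is
    exact and cheap: dCE/dz = (p - onehot)/n_pixels, and the Dice term is
    chained through the softmax Jacobian.
    """
    w_ce, w_dice = weights
    p = nn.softmax(logits, axis=1)
    n, c, h, w_ = logits.shape
    npix = n * h * w_
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)

    ce = float(
        -np.log(np.clip(np.take_along_axis(p, labels[:, None], 1)[:, 0], 1e-12, 1)).mean()
    )
    y = (labels > 0).astype(np.float64)
    p1 = p[:, 1]
    num = 2.0 * (p1 * y).sum() + eps
    den = p1.sum() + y.sum() + eps
    dl = 1.0 - num / den

    dlogits = w_ce * (p - onehot) / npix
    # d(dice)/dp1, then through softmax: dz_c = p_c (g_c - sum_k g_k p_k)
    g1 = w_dice * (num - 2.0 * y * den) / den**2
    g = np.zeros_like(p)
    g[:, 1] = g1
    dlogits += p * (g - (g * p).sum(axis=1, keepdims=True))
    return w_ce * ce + w_dice * dl, dlogits


# ----------------------------------------------------------- augmentation


@dataclass(frozen=True)
class AugmentSpec:
    """Menu of random transforms applied per training sample."""

    scale_range: tuple[float, float] = (0.8, 1.2)
    rotation_deg: float = 180.0
    flip_h: bool = True
    flip_v: bool = True
    elastic: bool = True
    elastic_mag_vox: float = 4.0
    noise_sigma: float = 0.02
    crop: int | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("scale_range must be positive with min <= max")


def _random_affine(shape, spec: AugmentSpec, rng):
    h, w = shape
    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    s = rng.uniform(*spec.scale_range)
    c, sn = np.cos(theta), np.sin(theta)
    mat = np.array([[c, -sn], [sn, c]]) / s
    # snap numerical noise so exact 90/180-degree rotations stay on-grid
    # (scipy's constant mode zeroes coordinates even 1e-16 outside the frame)
    mat[np.abs(mat) < 1e-12] = 0.0
    center = (np.asarray(shape) - 1) / 2.0
    offset = center - mat @ center
    return mat, offset


def augment_pair(
    image: np.ndarray,
    label: np.ndarray,
    spec: AugmentSpec = AugmentSpec(),
    rng: np.random.Generator | None = None,
):
    """Apply one random draw of the augmentation menu to a (C,H,W) slice stack
    and its (H,W) label; returns the augmented pair."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    image = np.asarray(image, dtype=np.float64)
    label = np.asarray(label)
    if image.shape[-2:] != label.shape:
        raise ValueError("image and label must share in-plane shape")

    identity_affine = spec.rotation_deg == 0 and spec.scale_range == (1.0, 1.0)
    if not identity_affine:
        mat, offset = _random_affine(label.shape, spec, rng)
        image = np.stack(
            [
                ndimage.affine_transform(ch, mat, offset, order=1, mode="constant")
                for ch in image
            ]
        )
        label = ndimage.affine_transform(label, mat, offset, order=0, mode="constant")

    if spec.flip_h and rng.random() < 0.5:
        image, label = image[..., ::-1], label[..., ::-1]
    if spec.flip_v and rng.random() < 0.5:
        image, label = image[..., ::-1, :], label[..., ::-1, :]

    if spec.elastic and spec.elastic_mag_vox > 0:
        h, w = label.shape
        disp = []
        for _ in range(2):
            d = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=8)
            peak = np.abs(d).max()
            disp.append(d * (spec.elastic_mag_vox / peak) if peak > 0 else d)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.array([yy + disp[0], xx + disp[1]])
        image = np.stack(
            [ndimage.map_coordinates(ch, coords, order=1, mode="constant") for ch in image]
        )
        label = ndimage.map_coordinates(label, coords, order=0, mode="constant")

    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, size=image.shape)

    if spec.crop is not None:
        cs = spec.crop
        h, w = label.shape
        if cs > h or cs > w:  # pad-then-crop fallback
            ph, pw = max(0, cs - h), max(0, cs - w)
            image = np.pad(image, ((0, 0), (0, ph), (0, pw)))
            label = np.pad(label, ((0, ph), (0, pw)))
            h, w = label.shape
        fg = np.argwhere(label > 0)
        if len(fg) and rng.random() < 0.8:
            cy, cx = fg[rng.integers(len(fg))]
            y0 = int(np.clip(cy - cs // 2, 0, h - cs))
            x0 = int(np.clip(cx - cs // 2, 0, w - cs))
        else:
            y0 = int(rng.integers(0, h - cs + 1))
            x0 = int(rng.integers(0, w - cs + 1))
        image = image[:, y0 : y0 + cs, x0 : x0 + cs]
        label = label[y0 : y0 + cs, x0 : x0 + cs]

    return np.ascontiguousarray(image), np.ascontiguousarray(label)


# -------------------------------------------------------------- training


@dataclass(frozen=True)
class TrainSpec:
    """Stage-specific optimization settings.

    ``crop_size`` defaults to the stage's training block size: 224 for the
    liver stage, 128 for the tumor stage (tests use smaller nets and crops).
    """

    stage: int = 1
    crop_size: int | None = None
    lr: float = 1e-3
    l2_coeff: float = 1e-4
    loss_weights: tuple[float, float] = (1.0, 1.0)
    epochs: int = 60
    batch_size: int = 8
    steps_per_epoch: int | None = None
    seed: int = 0

    def resolved_crop(self) -> int:
        if self.crop_size is not None:
            return self.crop_size
        return 224 if self.stage == 1 else 128

    def validate(self, depth: int) -> None:
        if self.lr < 0 or self.l2_coeff < 0:
            raise ValueError("lr and l2_coeff must be >= 0")
        div = 2 ** (depth - 1)
        if self.resolved_crop() % div:
            raise ValueError(
                f"crop_size {self.resolved_crop()} not divisible by 2^(depth-1)={div}"
            )


@dataclass
class TrainHistory:
    step_losses: list[float] = field(default_factory=list)
    epoch_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _snapshot(net: UNetPlusPlus):
    params = [p.data.copy() for p in net.parameters()]
    running = [
        {k: v.copy() for k, v in blk.layers[s][4].items()}
        for key in sorted(net.blocks)
        for s, blk in ((0, net.blocks[key]), (1, net.blocks[key]))
    ]
    return params, running


def _restore(net: UNetPlusPlus, snap) -> None:
    params, running = snap
    for p, d in zip(net.parameters(), params):
        p.data = d.copy()
    i = 0
    for key in sorted(net.blocks):
        for s in (0, 1):
            net.blocks[key].layers[s][4].update(
                {k: v.copy() for k, v in running[i].items()}
            )
            i += 1


def _eval_loss(net, cases, crop, weights):
    """Deterministic validation loss on the central crop of each foreground
    slice (up to 4 slices per case)."""
    losses = []
    for image, label in cases:
        zs = np.where(label.reshape(label.shape[0], -1).any(axis=1))[0]
        if len(zs) == 0:
            zs = [label.shape[0] // 2]
        for z in zs[:: max(1, len(zs) // 4)][:4]:
            img, lab = _center_crop(image[:, z], label[z], crop)
            logits = net.forward(img[None], training=False)[-1].data
            loss, _ = combined_loss_and_grad(logits, lab[None].astype(int), weights)
            losses.append(loss)
    return float(np.mean(losses))


def _center_crop(img, lab, cs):
    h, w = lab.shape
    if cs > h or cs > w:
        ph, pw = max(0, cs - h), max(0, cs - w)
        img = np.pad(img, ((0, 0), (0, ph), (0, pw)))
        lab = np.pad(lab, ((0, ph), (0, pw)))
        h, w = lab.shape
    y0, x0 = (h - cs) // 2, (w - cs) // 2
    return img[:, y0 : y0 + cs, x0 : x0 + cs], lab[y0 : y0 + cs, x0 : x0 + cs]


def train_stage(
    network: UNetPlusPlus,
    cases: list[tuple[np.ndarray, np.ndarray]],
    spec: TrainSpec,
    augment: AugmentSpec | None = None,
    val_cases: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> TrainHistory:
    """Train one cascade stage in place and return the loss history.

    ``cases`` holds ``(image (C,Z,Y,X), label (Z,Y,X) binary)`` volumes.
    Slices containing foreground are sampled preferentially (p = 0.8) so
    lesion/organ-bearing crops dominate each batch; the best-on-validation
    parameter snapshot is restored at the end when ``val_cases`` is given.
    Fully deterministic for a fixed ``spec.seed`` on one CPU thread.
    """
    spec.validate(network.spec.depth)
    crop = spec.resolved_crop()
    if augment is None:
        augment = AugmentSpec()
    rng = np.random.default_rng(spec.seed)

    fg_slices, all_slices = [], []
    for ci, (image, label) in enumerate(cases):
        if image.shape[1:] != label.shape:
            raise ValueError("image and label volumes must share grid")
        has_fg = label.reshape(label.shape[0], -1).any(axis=1)
        for z in range(label.shape[0]):
            all_slices.append((ci, z))
            if has_fg[z]:
                fg_slices.append((ci, z))
    if not all_slices:
        raise ValueError("no training slices")
    pool_fg = fg_slices or all_slices

    steps = spec.steps_per_epoch or max(1, len(pool_fg) // spec.batch_size)
    opt = nn.Adam(network.parameters(), lr=spec.lr, weight_decay=spec.l2_coeff)
    hist = TrainHistory()
    best_val = np.inf
    best_snap = None

    for epoch in range(spec.epochs):
        epoch_losses = []
        for _ in range(steps):
            imgs, labs = [], []
            for _ in range(spec.batch_size):
                pool = pool_fg if rng.random() < 0.8 else all_slices
                ci, z = pool[rng.integers(len(pool))]
                image, label = cases[ci]
                aug = AugmentSpec(**{**augment.__dict__, "crop": crop})
                img, lab = augment_pair(image[:, z], label[z], aug, rng)
                imgs.append(img)
                labs.append(lab.astype(int))
            x = np.stack(imgs)
            y = np.stack(labs)
            heads = network.forward(x, training=True)
            # deep supervision: average the head losses
            total = 0.0
            for h in heads:
                loss, dlogits = combined_loss_and_grad(
                    h.data, y, spec.loss_weights
                )
                total += loss / len(heads)
                h.backward(dlogits / len(heads))
            if not np.isfinite(total):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}, step {len(hist.step_losses)}; "
                    f"lr={spec.lr}, batch foreground fraction="
                    f"{np.mean([l.mean() for l in labs]):.4f}"
                )
            opt.step()
            opt.zero_grad()
            hist.step_losses.append(total)
            epoch_losses.append(total)
        hist.epoch_losses.append(float(np.mean(epoch_losses)))
        if val_cases is not None:
            vl = _eval_loss(network, val_cases, crop, spec.loss_weights)
            hist.val_losses.append(vl)
            if vl < best_val:
                best_val = vl
                best_snap = _snapshot(network)
                hist.best_epoch = epoch
    if best_snap is not None:
        _restore(network, best_snap)
    return hist
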
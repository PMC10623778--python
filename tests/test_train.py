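"""Losses, augmentation and the training loop."""

import numpy as np
import pytest

from hepaseg.train import (
    AugmentSpec,
    TrainSpec,
    augment_pair,
    combined_loss,
    combined_loss_and_grad,
    cross_entropy,
    dice_loss,
    train_stage,
)
from hepaseg.unetpp import NetworkSpec, build_network

NO_AUG = AugmentSpec(
    scale_range=(1.0, 1.0),
    rotation_deg=0.0,
    flip_h=False,
    flip_v=False,
    elastic=False,
    noise_sigma=0.0,
)


# ------------------------------------------------------------------ losses


def test_dice_loss_perfect_prediction_is_near_zero():
    y = np.zeros((8, 8))
    y[2:5, 2:5] = 1
    assert dice_loss(y, y) <= 1.0 / (2 * y.sum() + 1)  # eps-bounded


def test_dice_loss_hand_arithmetic_n8():
    # p uniformly 0.5 over n=8 pixels, y half ones:
    # 1 - (2*0.25n + 1) / (0.5n + 0.5n + 1) = 1 - 5/9
    p = np.full(8, 0.5)
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    assert dice_loss(p, y) == pytest.approx(1 - 5 / 9)
    assert dice_loss(p, y) == pytest.approx(0.4444444444444444)


def test_dice_loss_empty_convention():
    z = np.zeros((4, 4))
    assert dice_loss(z, z) == 0.0  # eps smoothing defines the empty case


def test_dice_loss_shape_mismatch_raises():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_combined_loss_zero_only_for_correct_onehot(rng):
    labels = (rng.random((1, 8, 8)) > 0.5).astype(int)
    onehot = np.stack([1 - labels, labels], axis=1).astype(float)
    near_zero = combined_loss(onehot, labels)
    assert near_zero < 0.02  # eps terms only
    wrong = combined_loss(onehot[:, ::-1], labels)
    assert wrong > 1.0


def test_combined_loss_and_grad_matches_finite_differences(rng):
    """Analytic gradient of the fused CE + Dice loss on a 4x4 toy."""
    logits = rng.normal(size=(1, 2, 4, 4))
    labels = (rng.random((1, 4, 4)) > 0.5).astype(int)
    loss, grad = combined_loss_and_grad(logits, labels, (1.0, 1.0))
    eps = 1e-6
    for idx in np.ndindex(logits.shape):
        logits[idx] += eps
        up, _ = combined_loss_and_grad(logits, labels, (1.0, 1.0))
        logits[idx] -= 2 * eps
        down, _ = combined_loss_and_grad(logits, labels, (1.0, 1.0))
        logits[idx] += eps
        assert grad[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-9)


def test_fused_loss_equals_public_functions(rng):
    logits = rng.normal(size=(2, 2, 8, 8))
    labels = (rng.random((2, 8, 8)) > 0.6).astype(int)
    from hepaseg.nn import softmax

    probs = softmax(logits, axis=1)
    fused, _ = combined_loss_and_grad(logits, labels, (1.0, 1.0))
    assert fused == pytest.approx(
        cross_entropy(probs, labels) + dice_loss(probs[:, 1], labels > 0)
    )


# ------------------------------------------------------------ augmentation


def test_disabled_augmentation_is_identity(rng):
    img = rng.random((2, 16, 16))
    lab = (rng.random((16, 16)) > 0.5).astype(np.int8)
    out_img, out_lab = augment_pair(img, lab, NO_AUG)
    assert np.array_equal(out_img, img)
    assert np.array_equal(out_lab, lab)


def test_double_180_rotation_restores_slice(rng):
    img = rng.random((1, 17, 17))
    lab = (rng.random((17, 17)) > 0.5).astype(np.int8)
    spec = AugmentSpec(**{**NO_AUG.__dict__, "rotation_deg": 180.0})

    class Fixed180:
        """Degenerate RNG: always draws the interval endpoint (180 deg)."""

        def uniform(self, lo, hi, size=None):
            return hi

        def random(self, size=None):
            return 1.0  # never flip

    i1, l1 = augment_pair(img, lab, spec, rng=Fixed180())
    i2, l2 = augment_pair(i1, l1, spec, rng=Fixed180())
    assert np.allclose(i2, img, atol=1e-8)
    assert np.array_equal(l2, lab)  # exact for nearest-neighbor labels


def test_augmentation_preserves_label_set(rng):
    img = rng.random((2, 32, 32))
    lab = (rng.random((32, 32)) > 0.5).astype(np.int8)
    spec = AugmentSpec(crop=16, seed=4)
    for trial in range(5):
        _, out = augment_pair(img, lab, spec, np.random.default_rng(trial))
        assert set(np.unique(out)) <= {0, 1}


def test_augmentation_seed_determinism(rng):
    img = rng.random((2, 24, 24))
    lab = (rng.random((24, 24)) > 0.5).astype(np.int8)
    spec = AugmentSpec(crop=16, seed=9)
    a = augment_pair(img, lab, spec)
    b = augment_pair(img, lab, spec)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_crop_larger_than_slice_pads(rng):
    img = rng.random((1, 10, 10))
    lab = np.zeros((10, 10), np.int8)
    spec = AugmentSpec(**{**NO_AUG.__dict__, "crop": 16})
    out_img, out_lab = augment_pair(img, lab, spec)
    assert out_img.shape == (1, 16, 16)
    assert out_lab.shape == (16, 16)


# --------------------------------------------------------------- training


def _toy_case(rng, shape=(1, 32, 32)):
    """A single repeated slice: bright rectangle on noise."""
    lab = np.zeros(shape, np.int8)
    lab[:, 8:20, 10:24] = 1
    img = np.stack([lab + 0.1 * rng.normal(size=shape) for _ in range(2)])
    return img, lab


def test_overfit_single_slice_halves_loss(rng):
    net = build_network(NetworkSpec(depth=2, base_filters=4), seed=0)
    case = _toy_case(rng)
    spec = TrainSpec(
        stage=1, crop_size=32, epochs=4, batch_size=2, steps_per_epoch=50, seed=0
    )
    hist = train_stage(net, [case], spec, augment=NO_AUG)
    assert hist.step_losses[-1] < 0.5 * hist.step_losses[0]


def test_saturated_overfit_reproduces_training_label(rng):
    """A tiny net trained to saturation on one repeated slice must reproduce
    that slice's label on >= 99% of pixels at argmax."""
    net = build_network(NetworkSpec(depth=2, base_filters=4), seed=1)
    image, label = _toy_case(rng)
    spec = TrainSpec(
        stage=1, crop_size=32, epochs=6, batch_size=2, steps_per_epoch=50, seed=1
    )
    train_stage(net, [(image, label)], spec, augment=NO_AUG)
    pred = net.predict_proba(image[:, 0][None])[0].argmax(axis=0)
    assert (pred == label[0]).mean() >= 0.99


def test_zero_learning_rate_freezes_loss(rng):
    net = build_network(NetworkSpec(depth=2, base_filters=4), seed=0)
    case = _toy_case(rng)
    spec = TrainSpec(
        stage=1, crop_size=32, lr=0.0, epochs=2, batch_size=2, steps_per_epoch=5, seed=0
    )
    hist = train_stage(net, [case], spec, augment=NO_AUG)
    # identical sample stream + frozen weights => identical losses
    assert np.ptp(hist.step_losses) < 1e-9


def test_training_is_deterministic(rng):
    case = _toy_case(rng)
    spec = TrainSpec(
        stage=1, crop_size=32, epochs=2, batch_size=2, steps_per_epoch=5, seed=7
    )
    hists = []
    for _ in range(2):
        net = build_network(NetworkSpec(depth=2, base_filters=4), seed=7)
        hists.append(train_stage(net, [case], spec, augment=AugmentSpec(seed=7)))
    assert hists[0].step_losses == hists[1].step_losses


def test_invalid_crop_divisibility_raises(rng):
    net = build_network(NetworkSpec(depth=3, base_filters=4), seed=0)
    with pytest.raises(ValueError):
        train_stage(net, [_toy_case(rng)], TrainSpec(stage=1, crop_size=30))


def test_stage_defaults_match_protocol():
    assert TrainSpec(stage=1).resolved_crop() == 224
    assert TrainSpec(stage=2).resolved_crop() == 128
    assert TrainSpec(stage=1).lr == 0.001
    assert TrainSpec(stage=1).l2_coeff == 0.0001
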
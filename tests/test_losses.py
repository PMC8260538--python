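"""Loss functions: closed-form spot values, invariances, reductions."""

import math

import numpy as np
import pytest

from surgseg.losses import (LossConfig, seg_loss, offset_loss, centroid_loss,
                            type_loss, joint_loss, class_weights_from_counts)
from surgseg.targets import build_targets


def _onehot_probs(target, n_classes, eps=1e-8):
    oh = (target[..., None] == np.arange(n_classes)).astype(np.float64)
    return ((oh + eps) / (1 + n_classes * eps)).astype(np.float32)


class TestSegLoss:
    def test_perfect_prediction_is_near_zero(self):
        t = np.zeros((8, 8), np.int64)
        t[2:5, 2:5] = 1
        assert seg_loss(_onehot_probs(t, 3), t) == pytest.approx(0.0, abs=1e-3)

    def test_uniform_two_class_ce_term(self):
        t = np.zeros((4, 4), np.int64)
        probs = np.full((4, 4, 2), 0.5, np.float32)
        # CE = log 2; DICE term computed directly for the uniform case
        inter0, den0 = 0.5 * 16, 0.5 * 16 + 16
        dice = 1 - 0.5 * ((2 * inter0 + 1) / (den0 + 1) + (2 * 0 + 1) / (0.5 * 16 + 0 + 1))
        assert seg_loss(probs, t) == pytest.approx(math.log(2) + dice, abs=1e-5)

    def test_total_miss_dice_tends_to_one(self):
        t = np.zeros((6, 6), np.int64)
        probs = _onehot_probs(np.ones((6, 6), np.int64), 2)
        cfg = LossConfig(dice_epsilon=1e-9)
        val = seg_loss(probs, t, cfg)
        # CE explodes toward -log(eps); DICE term alone approaches 1
        ce = -math.log(1e-6 / (1 + 2e-6))
        assert val - ce == pytest.approx(1.0, abs=1e-3)

    def test_shape_mismatch_raises(self):
        with pytest.raises(Exception):
            seg_loss(np.zeros((4, 4, 3), np.float32), np.zeros((5, 5), np.int64))


class TestOffsetLoss:
    def test_perfect_prediction(self):
        off = np.random.default_rng(0).normal(size=(6, 6, 2)).astype(np.float32)
        fg = np.ones((6, 6), bool)
        assert offset_loss(off, off, fg) == 0.0

    def test_single_foreground_pixel_l1(self):
        pred = np.zeros((5, 5, 2), np.float32)
        tgt = np.zeros((5, 5, 2), np.float32)
        fg = np.zeros((5, 5), bool)
        fg[2, 2] = True
        pred[2, 2] = (1.0, -1.0)
        assert offset_loss(pred, tgt, fg) == pytest.approx(2.0)

    def test_background_garbage_is_ignored(self):
        rng = np.random.default_rng(1)
        tgt = np.zeros((6, 6, 2), np.float32)
        fg = np.zeros((6, 6), bool)
        fg[1, 1] = True
        pred = rng.normal(size=(6, 6, 2)).astype(np.float32) * 100
        pred[1, 1] = 0.0
        assert offset_loss(pred, tgt, fg) == 0.0

    def test_empty_foreground_returns_zero(self):
        z = np.zeros((4, 4, 2), np.float32)
        assert offset_loss(z + 3.0, z, np.zeros((4, 4), bool)) == 0.0


class TestCentroidLoss:
    def test_positive_pixel_spot_value(self):
        # y=1, yhat=0.5, alpha=2, N=1: -(1-0.5)^2 log 0.5
        val = centroid_loss(np.array([[0.5]], np.float32),
                            np.array([[1.0]], np.float32), 1)
        assert val == pytest.approx(-(0.5 ** 2) * math.log(0.5), abs=1e-6)
        assert val == pytest.approx(0.17329, abs=1e-4)

    def test_penalty_reduced_negative_spot_value(self):
        # y = exp(-1/2) (Gaussian tail at distance sigma), yhat = 0.5
        y = math.exp(-0.5)
        val = centroid_loss(np.array([[0.5]], np.float32),
                            np.array([[y]], np.float32), 1)
        expected = -((1 - y) ** 4) * (0.5 ** 2) * math.log(0.5)
        assert val == pytest.approx(expected, abs=1e-6)
        assert val == pytest.approx(0.00415, abs=1e-4)

    def test_alpha_zero_on_binary_target_is_bce(self):
        rng = np.random.default_rng(3)
        y = (rng.random((8, 8)) < 0.1).astype(np.float32)
        yhat = np.clip(rng.random((8, 8)).astype(np.float32), 1e-6, 1 - 1e-6)
        cfg = LossConfig(alpha=0.0, beta=7.3)
        n = 4
        got = centroid_loss(yhat, y, n, cfg)
        # independent binary cross-entropy sum
        bce = -(y * np.log(yhat) + (1 - y) * np.log(1 - yhat)).sum() / n
        assert got == pytest.approx(bce, rel=1e-5)

    def test_empty_frame_uses_floor_one(self):
        y = np.zeros((4, 4), np.float32)
        yhat = np.full((4, 4), 0.2, np.float32)
        expected = -((0.2 ** 2) * math.log(0.8)) * 16
        assert centroid_loss(yhat, y, 0) == pytest.approx(expected, rel=1e-5)


class TestTypeLoss:
    def test_uniform_seven_classes(self):
        assert type_loss(np.full(7, 1 / 7, np.float32), 3) == \
            pytest.approx(math.log(7), abs=1e-5)

    def test_weights_from_counts(self):
        w = class_weights_from_counts({1: 10, 2: 5})
        assert w == pytest.approx([2 / 3, 4 / 3])
        assert w.mean() == pytest.approx(1.0)

    def test_weighted_equals_unweighted_for_unit_weights(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(7), size=4).astype(np.float32)
        labels = np.array([1, 3, 5, 7])
        assert type_loss(p, labels, np.ones(7)) == \
            pytest.approx(type_loss(p, labels), rel=1e-6)

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            type_loss(np.full(7, 1 / 7, np.float32), 8)


class TestJointLoss:
    def test_unit_components_with_default_gamma(self):
        assert joint_loss(1.0, 1.0, 1.0, 1.0, gamma=10.0) == 13.0

    def test_zero_components(self):
        assert joint_loss(0.0, 0.0, 0.0, 0.0) == 0.0


def test_losses_vanish_at_clamped_targets(sample_scenes):
    """All four losses are ~0 when predictions equal (clamped) targets."""
    for scene in sample_scenes[:5]:
        tb = build_targets(scene, sigma=3.0)
        n_inst = len(tb.centroid_list)
        assert seg_loss(_onehot_probs(tb.part_target, 5), tb.part_target) \
            == pytest.approx(0.0, abs=1e-3)
        assert offset_loss(tb.offset_target, tb.offset_target,
                           tb.foreground_mask) == 0.0
        binary_peaks = (tb.heatmap_target == 1.0).astype(np.float32)
        pred = np.clip(binary_peaks, 1e-6, 1 - 1e-6)
        assert centroid_loss(pred, binary_peaks, n_inst) == \
            pytest.approx(0.0, abs=1e-3)
        for i, t in scene.types.items():
            oh = np.full(7, 1e-8, np.float32)
            oh[t - 1] = 1.0
            assert type_loss(oh / oh.sum(), t) == pytest.approx(0.0, abs=1e-3)
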
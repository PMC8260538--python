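"""Scoring protocol: present-in-GT mIoU and mask mAP vs naive oracles."""

import numpy as np
import pytest

from surgseg.evaluation import (frame_miou, dataset_miou, mask_map, mask_iou,
                                instance_type_accuracy, DEFAULT_THRESHOLDS,
                                _average_precision)


def _square(shape, r0, c0, size, label=1):
    m = np.zeros(shape, np.int64)
    m[r0:r0 + size, c0:c0 + size] = label
    return m


class TestFrameMiou:
    def test_identity_scores_one(self):
        gt = _square((8, 8), 1, 1, 3, 1) + _square((8, 8), 5, 5, 2, 2)
        assert frame_miou(gt, gt, 2) == 1.0

    def test_shifted_square_is_one_third(self):
        gt = _square((6, 6), 2, 2, 2)
        pred = _square((6, 6), 2, 3, 2)
        # intersection 2, union 6
        assert frame_miou(pred, gt, 1) == pytest.approx(1 / 3)

    def test_class_absent_from_gt_is_not_scored(self):
        gt = _square((8, 8), 1, 1, 3, 1)
        pred = gt + _square((8, 8), 5, 5, 2, 3)  # spurious class 3
        assert frame_miou(pred, gt, 3) == 1.0

    def test_empty_gt_returns_absent(self):
        assert frame_miou(np.ones((4, 4), np.int64),
                          np.zeros((4, 4), np.int64), 1) is None

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, (10, 10))
        b = rng.integers(0, 3, (10, 10))
        assert frame_miou(a, b, 2) == pytest.approx(frame_miou(b, a, 2))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            frame_miou(np.zeros((3, 3)), np.zeros((4, 4)), 1)


class TestDatasetMiou:
    def test_mean_skips_absent_frames(self):
        gt1 = _square((6, 6), 0, 0, 3)
        gt2 = _square((6, 6), 2, 2, 2)
        empty = np.zeros((6, 6), np.int64)
        frames = [(gt1, gt1, 1),                        # 1.0
                  (_square((6, 6), 2, 3, 2), gt2, 1),   # 1/3... shifted
                  (np.ones((6, 6), np.int64), empty, 1)]  # absent
        # mean of 1.0 and 1/3
        assert dataset_miou(frames) == pytest.approx((1.0 + 1 / 3) / 2)

    def test_invariant_to_frame_order(self):
        rng = np.random.default_rng(1)
        frames = [(rng.integers(0, 3, (8, 8)), rng.integers(0, 3, (8, 8)), 2)
                  for _ in range(6)]
        assert dataset_miou(frames) == pytest.approx(
            dataset_miou(frames[::-1]))

    def test_all_absent_raises(self):
        z = np.zeros((4, 4), np.int64)
        with pytest.raises(ValueError):
            dataset_miou([(z, z, 1)])


def _mask(shape, r0, c0, h, w):
    m = np.zeros(shape, bool)
    m[r0:r0 + h, c0:c0 + w] = True
    return m


class TestMaskMap:
    def test_perfect_predictions_score_one(self):
        m1 = _mask((10, 10), 0, 0, 3, 3)
        m2 = _mask((10, 10), 6, 6, 3, 3)
        preds = [(m1, 1, 0.9), (m2, 2, 0.8)]
        gts = [(m1, 1), (m2, 2)]
        assert mask_map(preds, gts) == 1.0

    def test_iou_055_match_scores_two_tenths(self):
        # one GT, one prediction with IoU exactly 11/20 = 0.55:
        # TP at thresholds 0.50 and 0.55, FP at the other eight
        gt = _mask((20, 20), 0, 0, 4, 5)      # 20 px
        pred = _mask((20, 20), 0, 0, 4, 4)    # 16 px, overlap 16
        pred[4, 0:3] = True                   # 19 px, overlap 16
        # iou = 16 / (20 + 19 - 16) = 16/23... build exact 0.55 instead
        gt = np.zeros((20, 20), bool)
        gt[0, 0:20] = True                    # 20 px row
        pred = np.zeros((20, 20), bool)
        pred[0, 0:11] = True                  # overlap 11, union 20
        assert mask_iou(pred, gt) == pytest.approx(0.55)
        assert mask_map([(pred, 1, 0.9)], [(gt, 1)]) == pytest.approx(0.2)

    def test_wrong_class_scores_zero(self):
        m = _mask((8, 8), 1, 1, 4, 4)
        assert mask_map([(m, 2, 0.9)], [(m, 1)]) == 0.0

    def test_monotone_in_threshold_shift(self):
        rng = np.random.default_rng(3)
        preds, gts = [], []
        for k in range(4):
            g = _mask((16, 16), 3 * k, 0, 3, 6)
            p = _mask((16, 16), 3 * k, int(rng.integers(0, 3)), 3, 6)
            gts.append((g, 1))
            preds.append((p, 1, float(rng.random())))
        lo = mask_map(preds, gts, thresholds=np.arange(0.3, 0.75, 0.05))
        hi = mask_map(preds, gts, thresholds=np.arange(0.55, 1.0, 0.05))
        assert hi <= lo + 1e-12

    def test_matches_naive_reference_implementation(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n_p, n_g = rng.integers(1, 4), rng.integers(1, 4)
            preds, gts = [], []
            for _ in range(n_p):
                preds.append((_mask((12, 12), rng.integers(8),
                                    rng.integers(8), 4, 4),
                              int(rng.integers(1, 3)), float(rng.random())))
            for _ in range(n_g):
                gts.append((_mask((12, 12), rng.integers(8),
                                  rng.integers(8), 4, 4),
                            int(rng.integers(1, 3))))
            assert mask_map(preds, gts) == pytest.approx(
                _naive_map(preds, gts), abs=1e-12)


def _naive_map(preds, gts):
    """Plain-loop reference: greedy best-IoU matching per class/threshold,
    all-point interpolated AP, mean over GT classes and thresholds."""
    classes = sorted({c for _, c in gts})
    aps = []
    for cls in classes:
        cp = sorted([p for p in preds if p[1] == cls], key=lambda p: -p[2])
        cg = [g for g in gts if g[1] == cls]
        for thr in DEFAULT_THRESHOLDS:
            used = set()
            flags = []
            for pm, _, _ in cp:
                best_j, best_iou = None, thr
                for j, (gm, _) in enumerate(cg):
                    if j in used:
                        continue
                    iou = mask_iou(pm, gm)
                    if iou >= best_iou:
                        best_j, best_iou = j, iou
                if best_j is None:
                    flags.append(0.0)
                else:
                    used.add(best_j)
                    flags.append(1.0)
            aps.append(_average_precision(np.array(flags), len(cg)))
    grouped = np.array(aps).reshape(len(classes), len(DEFAULT_THRESHOLDS))
    return float(grouped.mean())


def test_instance_type_accuracy_counts_best_overlap():
    from surgseg.scene import LabeledScene
    from surgseg.scene import InstanceResult
    inst = np.zeros((8, 8), np.int64)
    inst[0:4, 0:4] = 1
    inst[4:8, 4:8] = 2
    part = (inst > 0).astype(np.int64)
    scene = LabeledScene(image=np.zeros((8, 8, 3)), instance_map=inst,
                         part_map=part, types={1: 3, 2: 5},
                         clasper_visible={1: True, 2: True})
    pred_map = np.zeros((8, 8), np.int64)
    pred_map[0:4, 0:4] = 2   # overlaps GT 1
    pred_map[4:8, 4:8] = 1   # overlaps GT 2
    res = InstanceResult(instance_map=pred_map, centroids=[],
                         class_label={1: 5, 2: 4})
    # GT 1 -> pred 2 (label 4 != 3 wrong); GT 2 -> pred 1 (label 5 == 5 right)
    assert instance_type_accuracy([res], [scene]) == 0.5
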
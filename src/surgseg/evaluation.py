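"""Challenge-style scoring: present-in-GT mIoU and mask mAP (IoU 0.50:0.95).

The mIoU protocol scores each frame as the mean IoU over the non-background
labels *present in that frame's ground truth* (a frame with no instrument is
skipped entirely), then averages over frames.  Mask mAP follows the COCO
convention: per class, predictions sorted by score are greedily matched
one-to-one to ground-truth masks at each IoU threshold in
{0.50, 0.55, ..., 0.95}; AP is the area under the all-point interpolated
precision-recall curve, and mAP averages over classes present in the ground
truth and over thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import LabeledScene
from .inference import InferenceConfig, predict_frame, predict_from_bundle

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class EvalReport:
    per_frame_miou: dict = field(default_factory=dict)
    types_miou: float = float("nan")
    parts_miou: float = float("nan")
    map_5095: float = float("nan")
    per_class_ap: dict = field(default_factory=dict)
    n_frames: int = 0
    binary_iou: float = float("nan")
    type_accuracy: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "types_miou": self.types_miou,
            "parts_miou": self.parts_miou,
            "map_5095": self.map_5095,
            "binary_iou": self.binary_iou,
            "type_accuracy": self.type_accuracy,
            "per_class_ap": {int(k): float(v)
                             for k, v in self.per_class_ap.items()},
            "n_frames": self.n_frames,
        }


# ------------------------------------------------------------------------ mIoU
def frame_miou(pred_label_map: np.ndarray, gt_label_map: np.ndarray,
               n_labels: int) -> float | None:
    """Mean IoU over the non-background labels present in the ground truth.

    Returns None ("absent") when the ground truth contains no non-background
    label; labels predicted but absent from GT are not scored.
    """
    pred = np.asarray(pred_label_map)
    gt = np.asarray(gt_label_map)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    present = [int(l) for l in np.unique(gt) if 0 < l <= n_labels]
    if not present:
        return None
    ious = []
    for l in present:
        p, g = pred == l, gt == l
        union = (p | g).sum()
        ious.append((p & g).sum() / union if union else 1.0)
    return float(np.mean(ious))


def dataset_miou(frames) -> float:
    """Mean of frame_miou over the frames where it is defined.

    ``frames`` is an iterable of (pred_label_map, gt_label_map, n_labels) or
    (pred, gt) with n_labels inferred from the data.
    """
    scores = []
    for item in frames:
        if len(item) == 3:
            pred, gt, n = item
        else:
            pred, gt = item
            n = int(max(np.max(pred), np.max(gt)))
        s = frame_miou(pred, gt, n)
        if s is not None:
            scores.append(s)
    if not scores:
        raise ValueError("no frame contains a present label")
    return float(np.mean(scores))


# -------------------------------------------------------------------- mask mAP
def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 0.0


def _average_precision(tp: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from score-ordered TP flags."""
    if n_gt == 0:
        return 0.0
    if tp.size == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope (monotone non-increasing from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r, ap = 0.0, 0.0
    for r, p in zip(recall, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mask_map(predictions, gts, thresholds=None,
             return_per_class: bool = False):
    """COCO-style mask mAP with class-aware greedy matching.

    predictions : list of (mask, class, score) or (frame, mask, class, score)
    gts         : list of (mask, class) or (frame, mask, class)
    Matching is restricted to items of the same frame (frame defaults to 0)
    and the same class; each prediction, in descending score order, takes the
    unmatched ground truth of highest IoU if that IoU meets the threshold.
    mAP averages over classes present in the ground truth and thresholds.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else tuple(thresholds)
    preds = [(p if len(p) == 4 else (0,) + tuple(p)) for p in predictions]
    gts = [(g if len(g) == 3 else (0,) + tuple(g)) for g in gts]
    classes = sorted({int(c) for _, _, c in gts})
    if not classes:
        return (0.0, {}) if return_per_class else 0.0

    per_class = {}
    for cls in classes:
        cp = sorted([p for p in preds if int(p[2]) == cls],
                    key=lambda p: -p[3])
        cg = [g for g in gts if int(g[2]) == cls]
        n_gt = len(cg)
        # cache IoUs between same-frame prediction/GT pairs
        ious = np.zeros((len(cp), n_gt), np.float64)
        for i, (pf, pm, _, _) in enumerate(cp):
            for j, (gf, gm, _) in enumerate(cg):
                if pf == gf:
                    ious[i, j] = mask_iou(pm, gm)
        aps = []
        for thr in thresholds:
            matched = np.zeros(n_gt, bool)
            tp = np.zeros(len(cp), np.float64)
            for i in range(len(cp)):
                cand = [(ious[i, j], j) for j in range(n_gt)
                        if not matched[j] and ious[i, j] >= thr]
                if cand:
                    _, j = max(cand, key=lambda t: (t[0], -t[1]))
                    matched[j] = True
                    tp[i] = 1.0
            aps.append(_average_precision(tp, n_gt))
        per_class[cls] = float(np.mean(aps))
    result = float(np.mean(list(per_class.values())))
    return (result, per_class) if return_per_class else result


# --------------------------------------------------------- model-level scoring
def label_map_from_result(result, n_classes: int) -> np.ndarray:
    """Paint each predicted instance's class label over its mask."""
    out = np.zeros_like(result.instance_map)
    for i, lab in result.class_label.items():
        out[result.instance_map == i] = lab
    return out


def type_label_map(scene: LabeledScene) -> np.ndarray:
    out = np.zeros_like(scene.instance_map)
    for i, t in scene.types.items():
        out[scene.instance_map == i] = t
    return out


def instance_type_accuracy(results, scenes) -> float:
    """Fraction of GT instances whose best-overlap predicted instance has the
    correct type; GT instances with no overlapping prediction count as wrong."""
    correct = total = 0
    for res, scene in zip(results, scenes):
        for gid in scene.instance_ids:
            total += 1
            gmask = scene.instance_map == gid
            best, best_ov = None, 0
            for pid in res.class_label:
                ov = (gmask & (res.instance_map == pid)).sum()
                if ov > best_ov:
                    best, best_ov = pid, ov
            if best is not None and res.class_label[best] == scene.types[gid]:
                correct += 1
    return correct / total if total else float("nan")


def evaluate_model(model, scenes, inference_config: InferenceConfig | None = None,
                   prior_fn=None) -> EvalReport:
    """Score a model on labeled scenes (no clasper filtering at evaluation).

    ``prior_fn(scene)`` may supply the per-frame presence prior for models
    built with ``use_prior``.
    """
    from .network import forward_many
    cfg = inference_config or InferenceConfig()
    n_classes = model.config.n_classes
    results, report = [], EvalReport(n_frames=len(scenes))
    bundles = forward_many(model, (s.image for s in scenes))
    for scene, pb in zip(scenes, bundles):
        prior = prior_fn(scene) if prior_fn is not None else None
        results.append(predict_from_bundle(model, pb, cfg, prior=prior))

    type_scores, part_scores, bin_scores = [], [], []
    preds_map, gts_map = [], []
    for k, (res, scene) in enumerate(zip(results, scenes)):
        gt_types = type_label_map(scene)
        s = frame_miou(label_map_from_result(res, n_classes), gt_types,
                       n_classes)
        if s is not None:
            type_scores.append(s)
            report.per_frame_miou[scene.frame_id or str(k)] = s
        pred_fg = res.instance_map != 0
        gt_fg = scene.instance_map != 0
        if gt_fg.any() or pred_fg.any():
            bin_scores.append(mask_iou(pred_fg, gt_fg))
        for pid, lab in res.class_label.items():
            preds_map.append((k, res.instance_map == pid, lab,
                              res.detection_score[pid]))
        for gid in scene.instance_ids:
            gts_map.append((k, scene.instance_map == gid, scene.types[gid]))

    if type_scores:
        report.types_miou = float(np.mean(type_scores))
    if bin_scores:
        report.binary_iou = float(np.mean(bin_scores))
    if gts_map:
        report.map_5095, report.per_class_ap = mask_map(
            preds_map, gts_map, return_per_class=True)
    report.type_accuracy = instance_type_accuracy(results, scenes)
    return report


def evaluate_parts(model, scenes) -> float:
    """Present-in-GT mIoU of the raw part-segmentation head."""
    from .network import forward_many
    scores = []
    for scene, pb in zip(scenes, forward_many(model,
                                              (s.image for s in scenes))):
        pred = pb.part_probs.argmax(axis=-1)
        s = frame_miou(pred, scene.part_map, int(scene.part_map.max()) or 1)
        if s is not None:
            scores.append(s)
    return float(np.mean(scores)) if scores else float("nan")
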
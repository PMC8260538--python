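"""Inference: centroid extraction, pixel-to-instance grouping, classification.

Instances are recovered without bounding boxes: heatmap peaks surviving a
3x3 non-maxima suppression (capped at 4, since at most three instruments
plus an ultrasound probe are ever visible) become centroids, and every
foreground pixel p joins the centroid nearest to p - y_o(p).  Each surviving
instance mask then gates the segmentation features f_seg for the shallow
type classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scene import InstanceResult
from .network import Model, forward, classify_instance

log = logging.getLogger(__name__)


@dataclass
class InferenceConfig:
    max_centroids: int = 4      # hard cap on instances per frame
    peak_threshold: float = 0.1  # minimum heatmap score for a peak
    nms_window: int = 3          # odd local-maximum window
    min_instance_pixels: int = 1  # drop smaller instances before classifying


def extract_centroids(heatmap: np.ndarray,
                      config: InferenceConfig | None = None) -> list:
    """NMS peak picking: keep local maxima above threshold, top-k by score.

    Returns [(row, col, score)] in descending score order; ties broken by
    (row, col) lexicographic order.
    """
    cfg = config or InferenceConfig()
    if cfg.nms_window % 2 == 0:
        raise ValueError("nms_window must be odd")
    hm = np.asarray(heatmap, dtype=np.float32)
    local_max = ndimage.maximum_filter(hm, size=cfg.nms_window,
                                       mode="constant", cval=-np.inf)
    peaks = np.argwhere((hm >= local_max) & (hm > cfg.peak_threshold))
    scored = sorted(((float(hm[r, c]), int(r), int(c)) for r, c in peaks),
                    key=lambda t: (-t[0], t[1], t[2]))
    return [(r, c, s) for s, r, c in scored[:cfg.max_centroids]]


def assign_instances(foreground_mask: np.ndarray, offsets: np.ndarray,
                     centroids: list) -> np.ndarray:
    """Group foreground pixels by nearest centroid of p - y_o(p).

    ``centroids`` is an ordered list of (row, col[, score]); the returned map
    holds 1-based indices into that order (0 = background).  Ties go to the
    smallest index.  An empty centroid list yields an all-background map.
    """
    fg = np.asarray(foreground_mask, bool)
    out = np.zeros(fg.shape, dtype=np.int64)
    if len(centroids) == 0:
        if fg.any():
            log.warning("foreground pixels present but no centroids extracted")
        return out
    pts = np.argwhere(fg).astype(np.float32)          # (M, 2)
    if pts.size == 0:
        return out
    off = np.asarray(offsets, np.float32)[fg]          # (M, 2)
    anchors = pts - off
    cents = np.asarray([[c[0], c[1]] for c in centroids], np.float32)  # (S, 2)
    d2 = ((anchors[:, None, :] - cents[None, :, :]) ** 2).sum(-1)
    out[fg] = d2.argmin(axis=1) + 1  # argmin takes the smallest index on ties
    return out


def predict_frame(model: Model, image: np.ndarray,
                  inference_config: InferenceConfig | None = None,
                  prior=None) -> InstanceResult:
    """Full per-frame pipeline: forward, group pixels, classify instances.

    Foreground is the argmax of the part head (any non-background part).
    Instances smaller than ``min_instance_pixels`` are dropped and ids are
    renumbered compactly in score order.  ``detection_score`` is the centroid
    score times the maximum class probability.  Never fails on empty scenes.
    """
    cfg = inference_config or InferenceConfig()
    pred = forward(model, image)
    return predict_from_bundle(model, pred, cfg, prior)


def predict_from_bundle(model: Model, pred, inference_config=None,
                        prior=None) -> InstanceResult:
    """Post-process an already-computed PredictionBundle (see predict_frame)."""
    cfg = inference_config or InferenceConfig()
    fg = pred.part_probs.argmax(axis=-1) != 0
    centroids = extract_centroids(pred.heatmap, cfg)
    inst = assign_instances(fg, pred.offsets, centroids)

    kept, new_map = [], np.zeros_like(inst)
    for idx in range(1, len(centroids) + 1):
        m = inst == idx
        if m.sum() >= max(cfg.min_instance_pixels, 1):
            kept.append((idx, m))
    result = InstanceResult(instance_map=new_map, centroids=[])
    semantic = model.config.variant == "semantic_type"
    for new_id, (idx, m) in enumerate(kept, start=1):
        new_map[m] = new_id
        r, c, score = centroids[idx - 1]
        result.centroids.append((r, c, score))
        if semantic:
            probs = _semantic_instance_probs(pred.type_logits, m,
                                             model.config.n_classes)
        else:
            probs = classify_instance(model, pred.f_seg, m, prior)
        result.class_probs[new_id] = probs
        result.class_label[new_id] = int(probs.argmax()) + 1
        result.detection_score[new_id] = float(score * probs.max())
    return result


def _semantic_instance_probs(type_logits: np.ndarray, mask: np.ndarray,
                             n_classes: int) -> np.ndarray:
    """Instance distribution for the semantic_type ablation: mean pixel-wise
    softmax over the instance mask, renormalized over the C non-background
    type classes."""
    logits = type_logits[mask]
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    probs = (e / e.sum(axis=-1, keepdims=True)).mean(axis=0)
    fg_probs = probs[1:n_classes + 1]
    total = fg_probs.sum()
    if total <= 0:
        return np.full(n_classes, 1.0 / n_classes, np.float32)
    return (fg_probs / total).astype(np.float32)
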
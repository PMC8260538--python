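"""Training losses: part segmentation (CE + soft DICE), masked L1 offsets,
penalty-reduced focal centroid loss, weighted per-instance type
cross-entropy, and their weighted joint sum.

Every loss is a pure function of predictions and targets.  Each accepts
either plain numpy arrays in per-frame layout (channels last, returning a
float) or autodiff :class:`~surgseg.autodiff.Tensor` batches in NCHW layout
(returning a Tensor), so the same code scores examples and drives training.

The focal-loss normalizer N is the number of ground-truth instances in the
frame (the convention of center-point detectors), with a floor of 1 for
empty frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class LossConfig:
    alpha: float = 2.0            # focal exponent on the prediction
    beta: float = 4.0             # penalty-reduction exponent on the target
    gamma: float = 10.0           # weight of the segmentation loss in the sum
    dice_epsilon: float = 1.0     # smoothing in the soft-DICE ratio
    clamp_epsilon: float = 1e-6   # probability clamp before logs
    class_weights: np.ndarray | None = None  # length-C, mean 1


def class_weights_from_counts(counts) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    ``counts`` is a length-C array (or dict class->count, classes 1-based) of
    per-instance type occurrences in the training split.  Classes that never
    occur get the mean of the defined weights (they contribute no gradient
    anyway).
    """
    if isinstance(counts, dict):
        n = max(counts)
        arr = np.zeros(n, dtype=np.float64)
        for c, v in counts.items():
            arr[c - 1] = v
    else:
        arr = np.asarray(counts, dtype=np.float64)
    w = np.zeros_like(arr)
    pos = arr > 0
    if not pos.any():
        return np.ones_like(arr, dtype=np.float32)
    w[pos] = 1.0 / arr[pos]
    w[pos] = w[pos] / w[pos].mean()
    w[~pos] = 1.0
    return w.astype(np.float32)


# ---------------------------------------------------------------- conversions
def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _probs4d(x) -> Tensor:
    """(H,W,C) numpy -> (1,C,H,W) Tensor; Tensors pass through."""
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float32)
    return Tensor(x.transpose(2, 0, 1)[None])


def _map3d(x) -> np.ndarray:
    x = np.asarray(x)
    return x[None] if x.ndim == 2 else x


def _scalar(out: Tensor, tensor_mode: bool):
    return out if tensor_mode else float(out.item())


# -------------------------------------------------------------------- seg loss
def seg_loss(part_probs, part_target, config: LossConfig | None = None):
    """Cross-entropy + soft DICE over the P+1 part classes.

    CE is the mean pixel-wise cross-entropy; DICE is 1 minus the mean (over
    all P+1 classes, background included) of the smoothed soft overlap ratio,
    computed per frame and averaged over the batch.
    """
    cfg = config or LossConfig()
    tensor_mode = _is_tensor(part_probs)
    p = _probs4d(part_probs)
    t = _map3d(part_target).astype(np.int64)
    n, c = p.shape[0], p.shape[1]
    eps = cfg.clamp_epsilon

    pt = ad.clip(ad.gather_channel(p, t), eps, 1.0)
    ce = -ad.tmean(ad.log(pt))

    onehot = (t[:, None] == np.arange(c)[None, :, None, None]).astype(np.float32)
    inter = ad.tsum(p * onehot, axis=(2, 3))            # (N, C)
    denom = ad.tsum(p, axis=(2, 3)) + onehot.sum(axis=(2, 3))
    de = cfg.dice_epsilon
    dice = 1.0 - ad.tmean((2.0 * inter + de) / (denom + de))
    return _scalar(ce + dice, tensor_mode)


# ----------------------------------------------------------------- offset loss
def offset_loss(pred_offsets, target_offsets, foreground_mask):
    """Mean L1 offset error over foreground pixels; background is ignored.

    Frames without any foreground contribute 0 (an instrument-free frame adds
    nothing to the objective).
    """
    tensor_mode = _is_tensor(pred_offsets)
    if isinstance(pred_offsets, Tensor):
        pred = pred_offsets
    else:
        pred = Tensor(np.asarray(pred_offsets, np.float32).transpose(2, 0, 1)[None])
    tgt = target_offsets.data if isinstance(target_offsets, Tensor) else \
        np.asarray(target_offsets, np.float32).transpose(2, 0, 1)[None]
    mask = _map3d(foreground_mask).astype(np.float32)[:, None]  # (N,1,H,W)

    err = ad.absolute(pred - tgt) * mask
    per_frame = ad.tsum(err, axis=(1, 2, 3))
    counts = np.maximum(mask.sum(axis=(1, 2, 3)), 1.0)
    return _scalar(ad.tmean(per_frame * (1.0 / counts)), tensor_mode)


# --------------------------------------------------------------- centroid loss
def centroid_loss(pred_heatmap, target_heatmap, n_instances,
                  config: LossConfig | None = None):
    """Penalty-reduced pixel-wise focal loss on the centroid heatmap.

    Pixels where the target equals exactly 1 are positives; everywhere else
    the negative term is down-weighted by (1 - y)^beta, which softens the
    penalty near true centers.  Normalized by the instance count N (floor 1)
    per frame.
    """
    cfg = config or LossConfig()
    tensor_mode = _is_tensor(pred_heatmap)
    pred = pred_heatmap if isinstance(pred_heatmap, Tensor) else \
        Tensor(_map3d(pred_heatmap).astype(np.float32))
    if pred.ndim == 2:
        pred = ad.reshape(pred, (1,) + tuple(pred.shape))
    y = target_heatmap.data if isinstance(target_heatmap, Tensor) else \
        np.asarray(target_heatmap, np.float32)
    y = y[None] if y.ndim == 2 else y

    eps = cfg.clamp_epsilon
    yhat = ad.clip(pred, eps, 1.0 - eps)
    pos = (y == 1.0).astype(np.float32)
    neg = 1.0 - pos
    pos_term = pos * (ad.power(1.0 - yhat, cfg.alpha) * ad.log(yhat))
    neg_term = neg * ((1.0 - y) ** cfg.beta *
                      (ad.power(yhat, cfg.alpha) * ad.log(1.0 - yhat)))
    per_frame = ad.tsum(pos_term + neg_term, axis=(1, 2))
    n_inst = np.maximum(np.atleast_1d(np.asarray(n_instances, np.float32)), 1.0)
    return _scalar(-ad.tmean(per_frame * (1.0 / n_inst)), tensor_mode)


# ------------------------------------------------------------------- type loss
def type_loss(class_probs, true_class, class_weights=None):
    """Weighted cross-entropy over instrument types, averaged over instances.

    ``true_class`` uses 1-based class labels (matching LabeledScene.types).
    """
    tensor_mode = _is_tensor(class_probs)
    p = class_probs if isinstance(class_probs, Tensor) else \
        Tensor(np.atleast_2d(np.asarray(class_probs, np.float32)))
    if p.ndim == 1:
        p = ad.reshape(p, (1, -1))
    labels = np.atleast_1d(np.asarray(true_class, np.int64)) - 1
    c = p.shape[1]
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"class label outside 1..{c}")
    w = np.ones(c, np.float32) if class_weights is None else \
        np.asarray(class_weights, np.float32)
    onehot = (labels[:, None] == np.arange(c)[None]).astype(np.float32)
    lp = ad.log(ad.clip(p, 1e-6, 1.0))
    per_inst = ad.tsum(lp * (onehot * w[labels][:, None]), axis=1)
    return _scalar(-ad.tmean(per_inst), tensor_mode)


# ------------------------------------------------------------------ joint loss
def joint_loss(l_t, l_o, l_c, l_s, gamma: float = 10.0):
    """L = L_t + L_o + L_c + gamma * L_s; gamma is large to privilege masks."""
    return l_t + l_o + l_c + gamma * l_s
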
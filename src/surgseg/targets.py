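"""Training-target construction: centroids, Gaussian heatmaps, offset fields.

Instance centers are the per-axis *median* of each instance's visible pixels
(robust to elongated, partially occluded shapes), rounded to integer pixels.
The centroid heatmap places an unnormalized Gaussian (default sigma = 20
pixels, quoted at full training resolution) at each centroid; overlapping
Gaussians combine by maximum, so the map is exactly 1 at every centroid.
Offsets store y_o(p) = p - c(i) at every foreground pixel, which makes the
nearest-centroid grouping rule p - y_o(p) = c(i) exact on ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import LabeledScene

DEFAULT_SIGMA = 20.0


@dataclass
class TargetBundle:
    part_target: np.ndarray        # (H, W) int in {0..P}
    offset_target: np.ndarray      # (H, W, 2) float, zero on background
    heatmap_target: np.ndarray     # (H, W) float in [0, 1]
    centroid_list: dict            # instance id -> (row, col) ints
    foreground_mask: np.ndarray    # (H, W) bool, == (part_target != 0)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def compute_centroid(pixels) -> tuple:
    """Per-axis median of a pixel set, rounded half-away-from-zero.

    For an even count the median is the mean of the two middle values before
    rounding.  Raises on an empty set.
    """
    pts = np.asarray(list(pixels), dtype=np.float64)
    if pts.size == 0:
        raise ValueError("empty instance")
    med = np.median(pts, axis=0)
    return (_round_half_away(med[0]), _round_half_away(med[1]))


def make_heatmap(centroids, shape, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Max-combined unnormalized Gaussians at the given (row, col) centers."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    out = np.zeros((h, w), dtype=np.float32)
    rows = np.arange(h, dtype=np.float32)[:, None]
    cols = np.arange(w, dtype=np.float32)[None, :]
    for c in centroids:
        r0, c0 = float(c[0]), float(c[1])
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError(f"centroid {(r0, c0)} outside {shape}")
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        np.maximum(out, np.exp(-d2 / (2.0 * sigma * sigma)), out=out)
    return out


def make_offsets(instance_map: np.ndarray, centroid_list: dict) -> np.ndarray:
    """Per-pixel offsets y_o(p) = p - centroid(instance(p)); zero outside fg."""
    inst = np.asarray(instance_map)
    h, w = inst.shape
    out = np.zeros((h, w, 2), dtype=np.float32)
    ids = [int(i) for i in np.unique(inst) if i != 0]
    missing = [i for i in ids if i not in centroid_list]
    if missing:
        raise ValueError(f"foreground ids without centroid: {missing}")
    rows, cols = np.indices((h, w), dtype=np.float32)
    for i in ids:
        m = inst == i
        cr, cc = centroid_list[i]
        out[m, 0] = rows[m] - cr
        out[m, 1] = cols[m] - cc
    return out


def build_targets(scene: LabeledScene, sigma: float = DEFAULT_SIGMA) -> TargetBundle:
    """Derive all dense training targets from one labeled scene.

    Disconnected visible fragments of an occluded instrument share one id, so
    the median is taken over all of its pixels regardless of connectivity.
    """
    inst = np.asarray(scene.instance_map)
    centroid_list = {}
    for i in [int(v) for v in np.unique(inst) if v != 0]:
        centroid_list[i] = compute_centroid(np.argwhere(inst == i))
    heat = make_heatmap(list(centroid_list.values()), inst.shape, sigma)
    offsets = make_offsets(inst, centroid_list)
    part = np.asarray(scene.part_map)
    return TargetBundle(
        part_target=part,
        offset_target=offsets,
        heatmap_target=heat,
        centroid_list=centroid_list,
        foreground_mask=part != 0,
    )
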
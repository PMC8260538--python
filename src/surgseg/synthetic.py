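"""Seeded generator of instrument-like scenes for desk-scale training/tests.

The generator reproduces the structural premises of endoscopic instrument
scenes that make instance typing hard for semantic segmentation:

* instruments are elongated — a capsule-shaped shaft enters from a random
  image border at a random angle and can span most of the frame;
* all classes share an *identical* shaft and wrist appearance and differ
  only in the geometry of the articulated tip (the clasper): a pixel-local
  classifier cannot determine the type away from the tip;
* instruments may overlap (later draws occlude earlier ones, which can split
  an instance into disconnected visible fragments sharing one id);
* the tip may leave the frame, in which case the clasper is not visible.

It does not attempt photorealism (no specularities, smoke, blood or video
coherence); textures are flat, white-noise or smooth blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scene import (LabeledScene, PART_SHAFT, PART_WRIST, PART_CLASPER,
                    derive_clasper_visibility, save_manifest)

# class -> tip template name; silhouettes chosen to stay pairwise
# distinguishable at the few-pixel scale the tiny preset renders at
# (low-frequency shape differences, no sub-2-px features)
TIP_STYLES = {1: "disc", 2: "ring", 3: "vee", 4: "jaw", 5: "tee",
              6: "cross", 7: "twin"}


@dataclass
class SynthConfig:
    height: int = 64
    width: int = 80
    n_instruments: tuple = (0, 4)    # inclusive range; never above 4
    n_classes: int = 7
    shaft_width_px: tuple = (5, 9)
    tip_size_px: tuple = (5, 7)
    tip_style_per_class: dict = field(
        default_factory=lambda: dict(TIP_STYLES))
    overlap_allowed: bool = True
    background_texture: str = "noise"   # flat | noise | blobs
    min_clasper_pixels: int = 10
    min_instrument_pixels: int = 30

    def __post_init__(self):
        if self.n_instruments[1] > 4:
            raise ValueError("at most 4 instruments per scene")
        styles = [self.tip_style_per_class[c]
                  for c in sorted(self.tip_style_per_class)]
        if len(set(styles)) != len(styles):
            raise ValueError("tip templates must be pairwise distinct")


FULL_PRESET = dict(height=256, width=320, shaft_width_px=(18, 30),
                   tip_size_px=(16, 24))


def _tip_mask(style: str, a: np.ndarray, b: np.ndarray, s: float) -> np.ndarray:
    """Tip template in local coordinates: a along the tool axis (positive
    pointing away from the wrist), b perpendicular; s is the tip scale.

    All templates are symmetric about the tool axis (so image flips map a
    class to itself) and differ in coarse silhouette — one lobe vs. two,
    solid vs. fenestrated, along-axis vs. across-axis extent — rather than
    in fine detail that would vanish at small render scales.
    """
    t = max(0.45 * s, 2.0)  # bar/prong half-thickness
    r2 = a ** 2 + b ** 2
    if style == "disc":       # solid round cup
        return r2 <= s ** 2
    if style == "ring":       # fenestrated jaw: annulus with a visible hole
        return ((r2 <= (1.25 * s) ** 2) & (r2 >= (0.62 * s) ** 2))
    if style == "vee":        # open scissors: two prongs diverging at ~35 deg
        ca, sa = np.cos(np.deg2rad(35.0)), np.sin(np.deg2rad(35.0))
        a0 = a + 1.1 * s      # apex sits behind the anchor: template centered
        out = np.zeros(a.shape, bool)
        for sign in (1.0, -1.0):
            u = a0 * ca + sign * b * sa
            v = -a0 * sa * sign + b * ca
            out |= (u >= -t) & (u <= 2.2 * s) & (np.abs(v) <= 0.8 * t)
        return out
    if style == "jaw":        # closed needle-driver jaw: solid along the axis
        return (np.abs(a) <= 1.2 * s) & (np.abs(b) <= 0.5 * s)
    if style == "tee":        # spatula: wide bar across the axis
        return (np.abs(a) <= 0.5 * s) & (np.abs(b) <= 1.7 * s)
    if style == "cross":      # two orthogonal bars
        return (((np.abs(a) <= t) & (np.abs(b) <= 1.5 * s))
                | ((np.abs(b) <= t) & (np.abs(a) <= 1.5 * s)))
    if style == "twin":       # bipolar tip: two side-by-side lobes
        return (((a ** 2 + (b - 0.95 * s) ** 2) <= (0.6 * s) ** 2)
                | ((a ** 2 + (b + 0.95 * s) ** 2) <= (0.6 * s) ** 2))
    raise ValueError(f"unknown tip style {style!r}")


def _render_instrument(shape, rng, cfg: SynthConfig, cls: int):
    """Render one instrument; returns (part_mask, intensity) arrays or None
    if the geometry leaves too few pixels inside the frame."""
    h, w = shape
    rows = np.arange(h, dtype=np.float32)[:, None]
    cols = np.arange(w, dtype=np.float32)[None, :]

    # anchor on the working tip: surgeons operate with the tip in view, so
    # the tip center is sampled in a slightly expanded frame (tips near or
    # beyond the border yield partially or fully hidden claspers); the shaft
    # runs backwards from it through a border at a random angle
    margin = 0.12 * min(h, w)
    tip_center = np.array([rng.uniform(-margin, h - 1 + margin),
                           rng.uniform(-margin, w - 1 + margin)])
    ang = rng.uniform(0.0, 2.0 * np.pi)
    d = np.array([np.sin(ang), np.cos(ang)], dtype=np.float32)
    perp = np.array([-d[1], d[0]], dtype=np.float32)

    diag = float(np.hypot(h, w))
    shaft_len = 1.5 * diag            # always enters from outside the frame
    wrist_len = rng.uniform(0.08, 0.14) * diag
    half_w = rng.uniform(*cfg.shaft_width_px) / 2.0
    tip_size = rng.uniform(*cfg.tip_size_px)
    start = tip_center - (shaft_len + wrist_len + tip_size * 0.9) * d

    dr = rows - start[0]
    dc = cols - start[1]
    u = dr * d[0] + dc * d[1]          # along-axis coordinate
    v = dr * perp[0] + dc * perp[1]    # across-axis coordinate

    shaft = (u >= 0) & (u <= shaft_len) & (np.abs(v) <= half_w)
    wrist = ((u > shaft_len) & (u <= shaft_len + wrist_len)
             & (np.abs(v) <= half_w * 1.15))
    tip_center_u = shaft_len + wrist_len + tip_size * 0.9
    style = cfg.tip_style_per_class[cls]
    tip = _tip_mask(style, u - tip_center_u, v, tip_size)

    part = np.zeros(shape, dtype=np.int64)
    part[shaft] = PART_SHAFT
    part[wrist] = PART_WRIST
    part[tip] = PART_CLASPER
    if (part != 0).sum() < cfg.min_instrument_pixels:
        return None

    # identical appearance across classes: per-part base intensity + noise
    intensity = np.zeros(shape, dtype=np.float32)
    intensity[shaft] = 0.70
    intensity[wrist] = 0.80
    intensity[tip] = 0.92
    intensity += (part != 0) * rng.normal(0.0, 0.02, shape).astype(np.float32)
    return part, intensity


def _background(shape, rng, texture: str) -> np.ndarray:
    h, w = shape
    base = np.full(shape, 0.25, dtype=np.float32)
    if texture == "flat":
        return base
    if texture == "noise":
        return base + rng.normal(0.0, 0.04, shape).astype(np.float32)
    if texture == "blobs":
        coarse = rng.normal(0.0, 1.0, (h // 8 + 1, w // 8 + 1))
        smooth = ndimage.zoom(coarse, 8, order=1)[:h, :w]
        return base + 0.08 * smooth.astype(np.float32)
    raise ValueError(f"unknown background texture {texture!r}")


def generate_scene(config: SynthConfig, seed) -> LabeledScene:
    """Draw one fully labeled scene; bit-identical for identical seeds."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    lo, hi = config.n_instruments
    k = int(rng.integers(lo, hi + 1))

    gray = _background((h, w), rng, config.background_texture)
    instance_map = np.zeros((h, w), dtype=np.int64)
    part_map = np.zeros((h, w), dtype=np.int64)
    types = {}
    next_id = 1
    attempts = 0
    while len(types) < k:
        cls = int(rng.integers(1, config.n_classes + 1))
        rendered = _render_instrument((h, w), rng, config, cls)
        attempts += 1
        if rendered is None:
            if attempts >= 100:
                k -= 1          # impossible geometry: retry with fewer
                attempts = 0
            continue
        part, intensity = rendered
        fg = part != 0
        if not config.overlap_allowed and (instance_map[fg] != 0).any():
            if attempts >= 100:
                k -= 1
                attempts = 0
            continue
        instance_map[fg] = next_id   # draw order: later instruments on top
        part_map[fg] = part[fg]
        gray[fg] = intensity[fg]
        types[next_id] = cls
        next_id += 1

    # drop ids fully occluded by later draws
    for i in list(types):
        if not (instance_map == i).any():
            del types[i]
    image = np.clip(gray, 0.0, 1.0)[..., None].repeat(3, axis=-1)
    # slight channel tint so the three channels are not identical
    image[..., 2] *= 0.95
    image[..., 0] *= 1.02
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    scene = LabeledScene(image=image, instance_map=instance_map,
                         part_map=part_map, types=types, clasper_visible={},
                         frame_id=f"synth_{seed}")
    scene.clasper_visible = derive_clasper_visibility(
        scene, config.min_clasper_pixels)
    return scene


def generate_scenes(config: SynthConfig, n_frames: int, seed: int) -> list:
    """n_frames independent scenes from one master seed (in memory)."""
    children = np.random.SeedSequence(seed).spawn(n_frames)
    scenes = []
    for i, ss in enumerate(children):
        s = generate_scene(config, ss)
        s.frame_id = f"synth_{seed}_{i:05d}"
        scenes.append(s)
    return scenes


def class_counts(scenes, n_classes: int = 7, visible_only: bool = False
                 ) -> np.ndarray:
    """Per-type instance counts (for inverse-frequency loss weights)."""
    counts = np.zeros(n_classes, dtype=np.int64)
    for s in scenes:
        for i, t in s.types.items():
            if visible_only and not s.clasper_visible.get(i, False):
                continue
            counts[t - 1] += 1
    return counts


def generate_dataset(config: SynthConfig, n_frames: int, seed: int,
                     out_dir) -> dict:
    """Write a PNG/JSON dataset split; returns manifest path and class counts."""
    scenes = generate_scenes(config, n_frames, seed)
    manifest = save_manifest(scenes, out_dir)
    return {"manifest": manifest, "n_frames": n_frames,
            "class_counts": class_counts(scenes, config.n_classes).tolist()}
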
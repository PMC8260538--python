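"""Core data model for labeled endoscopic scenes, predictions and results.

Coordinate and label conventions for the whole package live here:

* arrays are indexed image-style, 0-based ``(row, col)``, origin top-left;
* ``instance_map`` uses 0 for background and arbitrary positive integers for
  instrument instances (ground truth) or score-ordered ranks (predictions);
* ``part_map`` labels are 0 background, 1 shaft, 2 wrist, 3 clasper, 4 other;
* instrument types are 1..C (C = 7 by default); the tuple (0, 0) — background
  instance, background type — is implicit in the two maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PART_BACKGROUND = 0
PART_SHAFT = 1
PART_WRIST = 2
PART_CLASPER = 3
PART_OTHER = 4

DEFAULT_N_PARTS = 4
DEFAULT_N_CLASSES = 7

PART_NAMES = {0: "background", 1: "shaft", 2: "wrist", 3: "clasper", 4: "other"}


@dataclass
class LabeledScene:
    """One frame with full instance/part/type annotation.

    image : (H, W, 3) float array in [0, 1] (8-bit inputs are scaled on load)
    instance_map : (H, W) int array, 0 = background, 1..K instance ids
    part_map : (H, W) int array in {0..P}
    types : instance id -> class in {1..C}
    clasper_visible : instance id -> bool
    """

    image: np.ndarray
    instance_map: np.ndarray
    part_map: np.ndarray
    types: dict
    clasper_visible: dict
    frame_id: str = ""

    @property
    def shape(self):
        return self.instance_map.shape

    @property
    def instance_ids(self):
        ids = np.unique(self.instance_map)
        return [int(i) for i in ids if i != 0]


@dataclass
class PredictionBundle:
    """Raw network outputs for one frame (all spatial shapes H x W)."""

    part_logits: np.ndarray      # (H, W, P+1)
    part_probs: np.ndarray       # (H, W, P+1), softmax of part_logits
    offsets: np.ndarray          # (H, W, 2) (row, col) components in pixels
    heatmap: np.ndarray          # (H, W) in [0, 1]
    f_seg: np.ndarray            # (H, W, F) feature map feeding the classifier
    type_logits: np.ndarray | None = None  # (H, W, C+1), semantic_type variant


@dataclass
class InstanceResult:
    """Final per-frame output: instance map plus per-instance classification."""

    instance_map: np.ndarray               # (H, W), ids 1..|centroids|
    centroids: list                        # [(row, col, score)] descending score
    class_probs: dict = field(default_factory=dict)   # id -> (C,) distribution
    class_label: dict = field(default_factory=dict)   # id -> argmax class (1..C)
    detection_score: dict = field(default_factory=dict)  # id -> score


# ----------------------------------------------------------------- validation
def validate_scene(scene: LabeledScene,
                   n_parts: int = DEFAULT_N_PARTS,
                   n_classes: int = DEFAULT_N_CLASSES) -> list:
    """Check every LabeledScene invariant; return a list of violation strings.

    Returns an empty list iff the scene is consistent.  Never raises.
    """
    out = []
    inst, part = np.asarray(scene.instance_map), np.asarray(scene.part_map)
    if inst.shape != part.shape:
        out.append(f"shape mismatch: instance_map {inst.shape} vs part_map {part.shape}")
        return out
    if scene.image is not None and scene.image.shape[:2] != inst.shape:
        out.append(f"shape mismatch: image {scene.image.shape[:2]} vs maps {inst.shape}")

    mism = (inst != 0) != (part != 0)
    if mism.any():
        r, c = np.argwhere(mism)[0]
        out.append(f"foreground mismatch: instance_map/part_map disagree at pixel ({r}, {c})")
    if inst.min() < 0:
        out.append("negative instance id in instance_map")
    if part.min() < 0 or part.max() > n_parts:
        out.append(f"part label outside 0..{n_parts} in part_map")

    for i in sorted(np.unique(inst)):
        i = int(i)
        if i == 0:
            continue
        if i not in scene.types:
            out.append(f"missing type for instance id {i}")
        elif not (1 <= int(scene.types[i]) <= n_classes):
            out.append(f"type {scene.types[i]} of instance {i} outside 1..{n_classes}")
        if i not in scene.clasper_visible:
            out.append(f"missing clasper_visible entry for instance id {i}")
    return out


def derive_clasper_visibility(scene: LabeledScene, min_pixels: int = 10) -> dict:
    """id -> True iff the instance renders >= min_pixels clasper pixels.

    The visibility criterion itself (how many clasper pixels count as
    "visible") is this package's choice; a simple pixel-count threshold is
    used.  Monotone non-increasing in ``min_pixels``.
    """
    inst = np.asarray(scene.instance_map)
    clasper = np.asarray(scene.part_map) == PART_CLASPER
    out = {}
    for i in scene.instance_ids:
        out[i] = int(((inst == i) & clasper).sum()) >= min_pixels
    return out


# ----------------------------------------------------------------- dataset IO
def _imageio():
    import imageio.v3 as iio
    return iio


def save_scene(scene: LabeledScene, directory, stem: str) -> dict:
    """Write one scene as PNGs + return its manifest entry."""
    iio = _imageio()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.asarray(scene.image, dtype=np.float32) * 255.0, 0, 255
                   ).astype(np.uint8)
    paths = {
        "image": f"{stem}_image.png",
        "instance_map": f"{stem}_instances.png",
        "part_map": f"{stem}_parts.png",
    }
    iio.imwrite(directory / paths["image"], img8)
    iio.imwrite(directory / paths["instance_map"],
                scene.instance_map.astype(np.uint16))
    iio.imwrite(directory / paths["part_map"], scene.part_map.astype(np.uint8))
    return {
        "frame_id": scene.frame_id or stem,
        **paths,
        "types": {str(k): int(v) for k, v in scene.types.items()},
        "clasper_visible": {str(k): bool(v)
                            for k, v in scene.clasper_visible.items()},
    }


def load_scene(entry: dict, directory) -> LabeledScene:
    iio = _imageio()
    directory = Path(directory)
    image = iio.imread(directory / entry["image"]).astype(np.float32) / 255.0
    inst = iio.imread(directory / entry["instance_map"]).astype(np.int64)
    part = iio.imread(directory / entry["part_map"]).astype(np.int64)
    return LabeledScene(
        image=image, instance_map=inst, part_map=part,
        types={int(k): int(v) for k, v in entry["types"].items()},
        clasper_visible={int(k): bool(v)
                         for k, v in entry["clasper_visible"].items()},
        frame_id=entry.get("frame_id", ""),
    )


def save_manifest(scenes, directory, name: str = "manifest.json") -> Path:
    """Write a split of scenes + its JSON manifest; return the manifest path."""
    directory = Path(directory)
    entries = [save_scene(s, directory, s.frame_id or f"frame_{i:05d}")
               for i, s in enumerate(scenes)]
    path = directory / name
    path.write_text(json.dumps({"frames": entries}, indent=1))
    return path


def load_manifest(path) -> list:
    path = Path(path)
    data = json.loads(path.read_text())
    return [load_scene(e, path.parent) for e in data["frames"]]


# ------------------------------------------------------------ EndoVis adapter
def load_endovis_frame(dataset_dir, frame_index: int,
                       type_names=None) -> LabeledScene:
    """Best-effort reader for one frame of the EndoVis 2017 robotic-instrument
    challenge layout (``instrument_dataset_N/left_frames`` plus
    ``ground_truth/<Instrument>_labels``).  External data; the bundled tests
    never rely on it.

    Each ``ground_truth`` subfolder is treated as one instrument instance; its
    label PNG encodes parts as {0, 10 shaft, 20 wrist, 30 clasper, 40 other}.
    The instrument type is inferred from the folder name against
    ``type_names`` (type index = position in the list + 1).
    """
    iio = _imageio()
    dataset_dir = Path(dataset_dir)
    frame_name = f"frame{frame_index:03d}.png"
    image = iio.imread(dataset_dir / "left_frames" / frame_name)
    image = image.astype(np.float32) / 255.0
    h, w = image.shape[:2]
    instance_map = np.zeros((h, w), dtype=np.int64)
    part_map = np.zeros((h, w), dtype=np.int64)
    types, next_id = {}, 1
    type_names = type_names or []
    for sub in sorted((dataset_dir / "ground_truth").iterdir()):
        if not sub.is_dir():
            continue
        lab_path = sub / frame_name
        if not lab_path.exists():
            continue
        lab = np.asarray(iio.imread(lab_path))
        if lab.ndim == 3:
            lab = lab[..., 0]
        parts = np.clip(lab // 10, 0, 4)
        fg = parts > 0
        if not fg.any():
            continue
        instance_map[fg] = next_id
        part_map[fg] = parts[fg]
        t = 1
        for j, name in enumerate(type_names):
            if name.lower() in sub.name.lower():
                t = j + 1
                break
        types[next_id] = t
        next_id += 1
    scene = LabeledScene(image=image, instance_map=instance_map,
                         part_map=part_map, types=types, clasper_visible={},
                         frame_id=f"{dataset_dir.name}/{frame_name}")
    scene.clasper_visible = derive_clasper_visibility(scene)
    return scene
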
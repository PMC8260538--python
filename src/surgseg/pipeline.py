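"""Training pipeline: schedules, filtering rules, augmentation, ablations.

Training runs in two phases: the encoder and segmentation decoder are first
pretrained with the segmentation loss alone, then the whole network is
optimized end-to-end on the joint objective

    L = L_t + L_o + L_c + gamma * L_s,

with gamma large (default 10) to privilege good masks.  During training the
classifier is *teacher forced*: its input masks come from the ground-truth
instance maps, not from the still-unreliable predictions, and the f_seg
features it sees are perturbed with channel dropout.  Instruments whose
clasper is not visible are excluded from the classification loss, and images
without any visible clasper are discarded from training entirely; evaluation
never filters.

The optimizer is AdamW with a stepped learning-rate schedule (base rate
until a breakpoint epoch, then one tenth).  The ``tiny`` schedule scales the
full-resolution recipe (batch 24, 20-epoch pretrain, breakpoint 100) down to
desk scale (batch 8, 5-epoch pretrain, breakpoint 20, 30 epochs total) and
scales the heatmap sigma with the resolution.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .scene import LabeledScene, derive_clasper_visibility
from .targets import build_targets
from . import losses as L
from .network import Model, ModelConfig, build_model
from .inference import InferenceConfig
from .evaluation import evaluate_model


@dataclass
class TrainConfig:
    base_lr: float = 1e-3
    lr_after: float = 1e-4
    lr_breakpoint: int = 100     # epochs at base_lr before the drop
    cent_lr_breakpoint: int | None = None
    # (breakpoint for the centroid/offset branch; None follows
    # lr_breakpoint.  The branch does not feed the classifier, so it can
    # keep learning at full rate after the encoder/segmentation trunk is
    # slowed to stabilize f_seg.)
    batch_size: int = 24
    pretrain_epochs: int = 20    # seg decoder + encoder only
    total_epochs: int = 150
    resize: tuple = (512, 640)
    crop: tuple = (384, 480)
    crop_prob: float = 1.0       # fraction of batches trained on random crops
    # (the rest train on full frames, where offset/centroid targets are
    # unambiguous and instrument tips are never cut)
    sigma: float = 20.0          # heatmap Gaussian width at train resolution
    augment_flip: bool = True
    augment_rotation: bool = False
    rotation_deg: float = 30.0
    augment_photometric: bool = True
    photometric_jitter: float = 0.2
    teacher_forcing: bool = True
    max_classify_per_batch: int | None = None  # cap on instances per
    # classifier step (subsampled at random); None classifies every
    # teacher-forced instance in the batch
    dropout_fseg: float = 0.2
    clasper_min_pixels: int = 10
    weight_decay: float = 0.01
    classifier_lr: float | None = None  # fixed classifier-branch lr
    # (None: the classifier follows the trunk schedule.  A fixed value lets
    # the classifier keep learning at full rate after the trunk's lr drop,
    # when the features it consumes have stabilized.)
    val_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.crop[0] > self.resize[0] or self.crop[1] > self.resize[1]:
            raise ValueError("crop must fit inside resize")
        if self.pretrain_epochs > self.total_epochs:
            raise ValueError("pretrain_epochs must not exceed total_epochs")


def tiny_train_config(**overrides) -> TrainConfig:
    """Desk-scale schedule for the tiny preset on 64x80 synthetic scenes.

    The structure mirrors the full recipe (segmentation pretrain, joint
    phase, stepped lr) but re-balances it for training from scratch in 30
    epochs: a higher base rate; an early trunk breakpoint so f_seg
    stabilizes while the classifier — whose rate is held at base — keeps
    converging; a late breakpoint for the centroid/offset branch, which
    does not feed the classifier; and random crops on half the batches
    (full frames on the rest keep offset targets unambiguous and tips
    uncut).  Rotation is off: at 5-7 px tip scale, nearest-neighbour
    label rotation destroys the silhouettes that define the classes.
    """
    defaults = dict(base_lr=3e-3, lr_after=3e-4, batch_size=8,
                    pretrain_epochs=5, total_epochs=30, lr_breakpoint=12,
                    cent_lr_breakpoint=26, classifier_lr=3e-3,
                    resize=(64, 80), crop=(48, 64), crop_prob=0.5,
                    sigma=3.0, augment_rotation=False,
                    max_classify_per_batch=8)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def learning_rate(config: TrainConfig, epoch: int,
                  branch: str = "trunk") -> float:
    """lr(epoch), 1-based: base rate through the branch's breakpoint epoch,
    then the reduced rate.

    Branches: "trunk" (encoder, segmentation decoder, heads), "cent"
    (centroid/offset decoder and heads), "classifier" (fixed rate when
    ``classifier_lr`` is set).
    """
    if branch == "classifier" and config.classifier_lr is not None:
        return config.classifier_lr
    bp = config.lr_breakpoint
    if branch == "cent" and config.cent_lr_breakpoint is not None:
        bp = config.cent_lr_breakpoint
    return config.base_lr if epoch <= bp else config.lr_after


# -------------------------------------------------------------------- filtering
def filter_classification_batch(scenes):
    """Apply the clasper-visibility rules for training.

    Returns (kept_scenes, kept_ids): instruments without a visible clasper
    are dropped from the classification task, and scenes where *no*
    instrument has a visible clasper are discarded from training entirely.
    Evaluation code never calls this.
    """
    kept_scenes, kept_ids = [], []
    for s in scenes:
        ids = [i for i in s.instance_ids if s.clasper_visible.get(i, False)]
        if ids:
            kept_scenes.append(s)
            kept_ids.append(ids)
    return kept_scenes, kept_ids


# ----------------------------------------------------------------- augmentation
def resize_scene(scene: LabeledScene, size) -> LabeledScene:
    h, w = scene.instance_map.shape
    if (h, w) == tuple(size):
        return scene
    zr, zc = size[0] / h, size[1] / w
    image = ndimage.zoom(scene.image, (zr, zc, 1), order=1)
    inst = ndimage.zoom(scene.instance_map, (zr, zc), order=0)
    part = ndimage.zoom(scene.part_map, (zr, zc), order=0)
    return LabeledScene(image=image.astype(np.float32), instance_map=inst,
                        part_map=part, types=dict(scene.types),
                        clasper_visible=dict(scene.clasper_visible),
                        frame_id=scene.frame_id)


def augment_scene(scene: LabeledScene, config: TrainConfig,
                  rng: np.random.Generator,
                  do_crop: bool = True) -> LabeledScene:
    """Random crop (+ optional flip / rotation / photometric jitter).

    Clasper visibility is re-derived inside the crop; an instance whose tip
    the *crop itself* truncates is marked not-visible, because a cut tip
    shows misleading geometry (a three-prong fork with one prong cropped
    away looks like a two-prong one) and would poison the classification
    loss with label noise.  Types of instances that vanish are dropped.
    """
    from .scene import PART_CLASPER
    image = scene.image
    inst = scene.instance_map
    part = scene.part_map
    orig_clasper = inst * (part == PART_CLASPER)
    orig_counts = dict(zip(*np.unique(orig_clasper, return_counts=True)))
    if config.augment_rotation:
        ang = rng.uniform(-config.rotation_deg, config.rotation_deg)
        image = ndimage.rotate(image, ang, axes=(0, 1), reshape=False,
                               order=1, mode="nearest")
        inst = ndimage.rotate(inst, ang, reshape=False, order=0,
                              mode="constant")
        part = ndimage.rotate(part, ang, reshape=False, order=0,
                              mode="constant")
    # tips the rotation pushed over the border would show misleading
    # geometry; treat them like crop-truncated tips below
    clasper_full = inst * (part == PART_CLASPER)
    full_counts = dict(zip(*np.unique(clasper_full, return_counts=True)))
    for i, n0 in orig_counts.items():
        if i and full_counts.get(i, 0) < 0.9 * n0:
            full_counts[i] = -1  # poisoned: never matches the crop count
    h, w = inst.shape
    ch, cw = config.crop if do_crop else inst.shape
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    image = image[r0:r0 + ch, c0:c0 + cw]
    inst = inst[r0:r0 + ch, c0:c0 + cw]
    part = part[r0:r0 + ch, c0:c0 + cw]
    # both flips are label-preserving: instruments enter at arbitrary angles
    # and tip templates are symmetric about the tool axis
    if config.augment_flip:
        if rng.random() < 0.5:
            image, inst, part = image[:, ::-1], inst[:, ::-1], part[:, ::-1]
        if rng.random() < 0.5:
            image, inst, part = image[::-1], inst[::-1], part[::-1]

    if config.augment_photometric:
        j = config.photometric_jitter
        contrast = 1.0 + rng.uniform(-j, j)
        brightness = rng.uniform(-j, j) * 0.5
        image = np.clip((image - 0.5) * contrast + 0.5 + brightness, 0.0, 1.0)

    ids = [int(i) for i in np.unique(inst) if i != 0]
    types = {i: scene.types[i] for i in ids}
    out = LabeledScene(image=np.ascontiguousarray(image, dtype=np.float32),
                       instance_map=np.ascontiguousarray(inst),
                       part_map=np.ascontiguousarray(part),
                       types=types, clasper_visible={},
                       frame_id=scene.frame_id)
    vis = derive_clasper_visibility(out, config.clasper_min_pixels)
    crop_clasper = out.instance_map * (out.part_map == PART_CLASPER)
    crop_counts = dict(zip(*np.unique(crop_clasper, return_counts=True)))
    out.clasper_visible = {
        i: bool(vis[i]) and crop_counts.get(i, 0) == full_counts.get(i, 0)
        for i in ids}
    return out


def presence_prior(scene: LabeledScene, n_classes: int) -> np.ndarray:
    """Binary instruments-attached vector (the kinematics prior)."""
    v = np.zeros(n_classes, dtype=np.float32)
    for t in scene.types.values():
        v[t - 1] = 1.0
    return v


# -------------------------------------------------------------------- optimizer
class AdamW:
    """AdamW with decoupled weight decay (decay applied to >=2-D weights only).

    Parameters whose gradient is None in a step are left untouched, which is
    what restricts the pretraining phase to the encoder + segmentation
    decoder: unused branches receive no gradient.
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01, lr_scales=None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.lr_scales = [1.0] * len(self.params) if lr_scales is None \
            else list(lr_scales)
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v, scale in zip(self.params, self.m, self.v,
                                  self.lr_scales):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * scale * update


# ------------------------------------------------------------------- train step
def _batch_tensors(scenes, config: TrainConfig, binary: bool):
    """Stack crops into training arrays + targets."""
    xs, part_t, off_t, heat_t, fg, n_inst = [], [], [], [], [], []
    for s in scenes:
        tb = build_targets(s, sigma=config.sigma)
        xs.append(s.image.transpose(2, 0, 1))
        pt = tb.part_target
        part_t.append((pt != 0).astype(np.int64) if binary else pt)
        off_t.append(tb.offset_target.transpose(2, 0, 1))
        heat_t.append(tb.heatmap_target)
        fg.append(tb.foreground_mask)
        n_inst.append(len(tb.centroid_list))
    return (np.stack(xs).astype(np.float32), np.stack(part_t),
            np.stack(off_t).astype(np.float32),
            np.stack(heat_t).astype(np.float32), np.stack(fg), np.array(n_inst))


def _classification_inputs(scenes, config: TrainConfig, n_classes: int):
    """Teacher-forced classifier inputs for a batch of crops:
    (frame indices, instance masks, labels, priors)."""
    rows, masks, labels, priors = [], [], [], []
    for n, s in enumerate(scenes):
        for i in s.instance_ids:
            if not s.clasper_visible.get(i, False):
                continue
            rows.append(n)
            masks.append(s.instance_map == i)
            labels.append(s.types[i])
            priors.append(presence_prior(s, n_classes))
    if not rows:
        return None
    return (np.array(rows), np.stack(masks), np.array(labels),
            np.stack(priors))


@dataclass
class TrainResult:
    model: Model
    history: list
    best_path: Path | None = None
    last_path: Path | None = None
    best_model: Model | None = None


def train(model_config: ModelConfig, train_config: TrainConfig,
          dataset, val_scenes=None, out_dir=None,
          on_classifier_batch=None) -> TrainResult:
    """Two-phase training on labeled scenes.

    ``dataset`` is a list of LabeledScene (or a manifest path).  Returns the
    final model, the per-epoch loss/metric history, and — when ``out_dir``
    and ``val_scenes`` are given — both the best-by-validation and the final
    checkpoints (validation-selected scores are optimistic, so both are
    kept).  ``on_classifier_batch`` is an instrumentation hook called with
    (epoch, frame_rows, masks, labels) before every classifier step.
    """
    if isinstance(dataset, (str, Path)):
        from .scene import load_manifest
        dataset = load_manifest(dataset)
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)

    scenes = [resize_scene(s, cfg.resize) for s in dataset]
    scenes, _ = filter_classification_batch(scenes)
    if not scenes:
        raise ValueError("no training scene has a visible clasper")

    n_classes = model_config.n_classes
    from .synthetic import class_counts
    weights = L.class_weights_from_counts(
        np.maximum(class_counts(scenes, n_classes, visible_only=True), 0))
    loss_cfg = L.LossConfig(class_weights=weights)
    binary = model_config.variant == "binary_seg"
    semantic = model_config.variant == "semantic_type"

    model = build_model(model_config)
    branch_of = {}
    for mod, branch in ((model.classifier, "classifier"),
                        (model.cent_decoder, "cent"),
                        (model.offset_head, "cent"),
                        (model.heatmap_head, "cent")):
        if mod is not None:
            for p in mod.parameters():
                branch_of[id(p)] = branch
    if model.cent_decoder is None:  # single decoder: heads follow the trunk
        for p in (*model.offset_head.parameters(),
                  *model.heatmap_head.parameters()):
            branch_of.pop(id(p), None)
    branches = [branch_of.get(id(p), "trunk") for p in model.parameters()]
    opt = AdamW(model.parameters(), lr=1.0,
                weight_decay=cfg.weight_decay)
    history, best_score, best_model = [], -np.inf, None
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, cfg.total_epochs + 1):
        t0 = time.time()
        opt.lr = 1.0
        opt.lr_scales = [learning_rate(cfg, epoch, b) for b in branches]
        pretrain = epoch <= cfg.pretrain_epochs
        order = rng.permutation(len(scenes))
        sums = {"seg": 0.0, "offset": 0.0, "centroid": 0.0, "type": 0.0,
                "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            do_crop = bool(rng.random() < cfg.crop_prob)
            crops = [augment_scene(scenes[i], cfg, rng, do_crop) for i in idx]
            x, part_t, off_t, heat_t, fg, n_inst = _batch_tensors(
                crops, cfg, binary)
            out = model.forward_batch(Tensor(x), seg_only=pretrain)
            part_probs = ad.softmax(out["part_logits"], axis=1)
            l_s = L.seg_loss(part_probs, part_t, loss_cfg)
            if pretrain:
                loss = l_s
                l_o = l_c = l_t = 0.0
            else:
                l_o = L.offset_loss(out["offsets"], Tensor(off_t), fg)
                heat = ad.reshape(out["heatmap"],
                                  (x.shape[0], x.shape[2], x.shape[3]))
                l_c = L.centroid_loss(heat, Tensor(heat_t), n_inst, loss_cfg)
                l_t = _type_term(model, out, crops, cfg, loss_cfg,
                                 n_classes, rng, epoch, semantic,
                                 on_classifier_batch)
                loss = L.joint_loss(l_t, l_o, l_c, l_s, loss_cfg.gamma)

            if not np.isfinite(float(loss)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: seg={float(l_s):.4g} "
                    f"off={float(l_o):.4g} cent={float(l_c):.4g} "
                    f"type={float(l_t):.4g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums["seg"] += float(l_s)
            sums["offset"] += float(l_o)
            sums["centroid"] += float(l_c)
            sums["type"] += float(l_t)
            sums["total"] += float(loss)
            n_batches += 1

        entry = {"epoch": epoch, "phase": "pretrain" if pretrain else "joint",
                 "lr": learning_rate(cfg, epoch),
                 "seconds": round(time.time() - t0, 2),
                 **{f"loss_{k}": v / max(n_batches, 1)
                    for k, v in sums.items()}}
        if val_scenes is not None and (
                epoch % cfg.val_interval == 0 or epoch == cfg.total_epochs):
            rep = evaluate_model(model, val_scenes, InferenceConfig())
            entry["val_binary_iou"] = rep.binary_iou
            entry["val_type_accuracy"] = rep.type_accuracy
            entry["val_types_miou"] = rep.types_miou
            score = np.nan_to_num(rep.types_miou, nan=rep.binary_iou)
            if score > best_score:
                best_score = score
                best_model = _clone(model)
        history.append(entry)
        if out_dir is not None:
            with open(out_dir / "train_log.jsonl", "a") as f:
                f.write(json.dumps(entry) + "\n")

    result = TrainResult(model=model, history=history, best_model=best_model)
    if out_dir is not None:
        result.last_path = out_dir / "checkpoint_last.npz"
        model.save(result.last_path)
        if best_model is not None:
            result.best_path = out_dir / "checkpoint_best.npz"
            best_model.save(result.best_path)
        (out_dir / "train_config.json").write_text(json.dumps(asdict(cfg)))
    return result


def _clone(model: Model) -> Model:
    clone = build_model(model.config)
    for (_, p), (_, q) in zip(clone.named_parameters(),
                              model.named_parameters()):
        p.data = q.data.copy()
    return clone


def _type_term(model, out, crops, cfg, loss_cfg, n_classes, rng, epoch,
               semantic, hook):
    """Classification term of the joint loss for one batch."""
    if semantic:
        type_t = np.stack([_type_map(s) for s in crops])
        probs = ad.softmax(out["type_logits"], axis=1)
        return L.seg_loss(probs, type_t, loss_cfg)
    ci = _classification_inputs(crops, cfg, n_classes)
    if ci is None:
        return 0.0
    rows, masks, labels, priors = ci
    cap = cfg.max_classify_per_batch
    if cap is not None and len(rows) > cap:
        pick = rng.choice(len(rows), cap, replace=False)
        rows, masks, labels, priors = (rows[pick], masks[pick],
                                       labels[pick], priors[pick])
    if hook is not None:
        hook(epoch, rows, masks, labels)
    f_seg = ad.channel_dropout(out["f_seg"], cfg.dropout_fseg, rng)
    feats = ad.take_rows(f_seg, rows) * masks[:, None].astype(np.float32)
    logits = model.classify_batch(
        feats, priors if model.config.use_prior else None)
    return L.type_loss(ad.softmax(logits, axis=1), labels,
                       loss_cfg.class_weights)


def _type_map(scene: LabeledScene) -> np.ndarray:
    out = np.zeros_like(scene.instance_map)
    for i, t in scene.types.items():
        out[scene.instance_map == i] = t
    return out


# --------------------------------------------------------------------- ablation
def run_ablation(variants, model_config: ModelConfig,
                 train_config: TrainConfig, train_scenes, eval_scenes,
                 use_prior_variants=()) -> dict:
    """Train each variant with identical data/seed and score it.

    Returns {variant: {"types_miou": .., "map_5095": .., ...}}.
    """
    results = {}
    for variant in variants:
        mc = ModelConfig(**{**asdict(model_config), "variant": variant,
                            "use_prior": variant in use_prior_variants})
        res = train(mc, train_config, train_scenes)
        prior_fn = (lambda s: presence_prior(s, mc.n_classes)) \
            if mc.use_prior else None
        rep = evaluate_model(res.model, eval_scenes, prior_fn=prior_fn)
        results[variant] = rep.as_dict()
    return results


def format_ablation_table(results: dict) -> str:
    cols = ["types_miou", "map_5095", "binary_iou", "type_accuracy"]
    lines = ["variant".ljust(18) + "".join(c.rjust(15) for c in cols)]
    for variant, metrics in results.items():
        row = variant.ljust(18)
        for c in cols:
            v = metrics.get(c, float("nan"))
            row += f"{v:15.4f}"
        lines.append(row)
    return "\n".join(lines)
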
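"""Network architecture: shared encoder, two decoder heads, shallow classifier.

The encoder is a plain conv-norm-relu pyramid (2x2 max-pool between stages)
with group normalization throughout, so behaviour is independent of batch
size.  Two lightweight decoders (upsample + two conv-norm-relu per block,
long skip concatenations from the last three encoder stages, and a final
three-layer conv block) produce

* the part segmentation logits (shaft / wrist / clasper / other + background)
  together with the feature map ``f_seg`` that feeds the classifier, and
* the centroid heatmap (sigmoid) and per-pixel offset vectors.

The instance classifier is a shallow CNN — four conv-norm-relu layers with
stride-2 max-pooling, then a global max-pool and a fully connected layer —
applied to ``f_seg`` masked by one instance mask at a time.  With ``use_prior`` a binary instrument-presence vector is
concatenated to the pooled feature and a second FC layer is added.

Two presets are provided: ``full`` (EfficientNet-B0-like stage widths,
stride 32) and ``tiny`` (three stages, widths 16/32/64, stride 8) sized for
CPU training on the synthetic scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .scene import PredictionBundle, DEFAULT_N_PARTS, DEFAULT_N_CLASSES

VARIANTS = ("proposed", "single_decoder", "binary_seg", "semantic_type")


@dataclass
class ModelConfig:
    preset: str = "tiny"
    n_parts: int = DEFAULT_N_PARTS
    n_classes: int = DEFAULT_N_CLASSES
    f_seg_channels: int = 32
    variant: str = "proposed"
    use_prior: bool = False
    norm_groups: int = 8
    dropout_fseg: float = 0.2
    classifier_hidden: int = 64
    init_seed: int = 0


_PRESETS = {
    # stem width, per-stage widths (one 2x2 pool after each stage),
    # decoder block widths (deepest first), final-block width, classifier widths
    "tiny": dict(stem=16, stages=(16, 32, 64), depths=(1, 1, 1),
                 dec=(32, 16, 8), final=8, cent_final=16,
                 cls=(16, 32, 32, 64)),
    "full": dict(stem=32, stages=(16, 24, 40, 112, 320), depths=(1, 2, 2, 3, 3),
                 dec=(256, 128, 64, 48, 32), final=32, cent_final=32,
                 cls=(32, 64, 64, 128)),
}


# ----------------------------------------------------------------- primitives
class Module:
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        w = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias)


class GroupNorm2d(Module):
    def __init__(self, channels: int, groups: int):
        g = groups
        while channels % g:
            g //= 2
        self.groups = max(g, 1)
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.groupnorm(x, self.gamma, self.beta, self.groups)


class ConvNormRelu(Module):
    def __init__(self, cin, cout, rng, groups=8, k=3):
        self.conv = Conv2d(cin, cout, k, rng)
        self.norm = GroupNorm2d(cout, groups)

    def __call__(self, x):
        return ad.relu(self.norm(self.conv(x)))


class Linear(Module):
    def __init__(self, cin, cout, rng):
        w = rng.standard_normal((cin, cout)) * np.sqrt(1.0 / cin)
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.matmul(x, self.weight) + self.bias


# -------------------------------------------------------------------- encoder
class Encoder(Module):
    def __init__(self, preset: dict, rng, groups):
        self.stem = ConvNormRelu(3, preset["stem"], rng, groups)
        self.stages = []
        cin = preset["stem"]
        for width, depth in zip(preset["stages"], preset["depths"]):
            blocks = []
            for d in range(depth):
                blocks.append(ConvNormRelu(cin if d == 0 else width, width,
                                           rng, groups))
            self.stages.append(blocks)
            cin = width
        # flatten for parameter registration
        self._blocks = [b for st in self.stages for b in st]

    def named_parameters(self, prefix: str = ""):
        yield from self.stem.named_parameters(f"{prefix}stem.")
        for i, b in enumerate(self._blocks):
            yield from b.named_parameters(f"{prefix}block{i}.")

    def __call__(self, x):
        x = self.stem(x)
        skips = []
        for blocks in self.stages:
            for b in blocks:
                x = b(x)
            skips.append(x)
            x = ad.maxpool2(x)
        return x, skips  # bottleneck at stride 2**n_stages, pre-pool skips


class Decoder(Module):
    """Upsample x2 + two conv-norm-relu per block; final 3-layer conv block.

    Long skips (channel concatenation) come from the last three encoder
    stages; deeper decoder blocks in the full preset run without skips.
    ``out_channels`` sets the width of the last conv of the final block
    (this is ``f_seg`` for the segmentation decoder).
    """

    def __init__(self, bottleneck_ch, skip_chs, dec_widths, final_width,
                 out_channels, rng, groups):
        self.blocks = []
        cin = bottleneck_ch
        self.n_skips = min(3, len(skip_chs))
        used = list(skip_chs[::-1][:self.n_skips])  # deepest first
        for i, width in enumerate(dec_widths):
            skip = used[i] if i < len(used) else 0
            self.blocks.append([
                ConvNormRelu(cin + skip, width, rng, groups),
                ConvNormRelu(width, width, rng, groups),
            ])
            cin = width
        self.final = [
            ConvNormRelu(cin, final_width, rng, groups),
            ConvNormRelu(final_width, final_width, rng, groups),
            ConvNormRelu(final_width, out_channels, rng, groups),
        ]
        self._flat = [b for blk in self.blocks for b in blk] + self.final

    def named_parameters(self, prefix: str = ""):
        for i, b in enumerate(self._flat):
            yield from b.named_parameters(f"{prefix}layer{i}.")

    def __call__(self, x, skips):
        deep_first = skips[::-1][:self.n_skips]
        for i, (c1, c2) in enumerate(self.blocks):
            x = ad.upsample2(x)
            if i < len(deep_first):
                x = ad.concat([x, deep_first[i]], axis=1)
            x = c2(c1(x))
        for layer in self.final:
            x = layer(x)
        return x


class Classifier(Module):
    """Shallow CNN over the masked f_seg: four conv-norm-relu layers with
    stride-2 max-pooling after the second and fourth, a global max-pool, and
    one FC layer (two when a presence prior is given).

    Pooling only after the first and last conv keeps enough spatial
    resolution for the small tip geometry that distinguishes instrument
    types, while the global max-pool still collapses the arbitrary instance
    extent.
    """

    pool_after = (0, 3)

    def __init__(self, cfg: ModelConfig, rng):
        widths = _PRESETS[cfg.preset]["cls"]
        self.convs = []
        cin = cfg.f_seg_channels
        for w in widths:
            self.convs.append(ConvNormRelu(cin, w, rng, cfg.norm_groups))
            cin = w
        self.use_prior = cfg.use_prior
        if cfg.use_prior:
            self.fc1 = Linear(cin + cfg.n_classes, cfg.classifier_hidden, rng)
            self.fc2 = Linear(cfg.classifier_hidden, cfg.n_classes, rng)
        else:
            self.fc = Linear(cin, cfg.n_classes, rng)

    def named_parameters(self, prefix: str = ""):
        for i, c in enumerate(self.convs):
            yield from c.named_parameters(f"{prefix}conv{i}.")
        if self.use_prior:
            yield from self.fc1.named_parameters(f"{prefix}fc1.")
            yield from self.fc2.named_parameters(f"{prefix}fc2.")
        else:
            yield from self.fc.named_parameters(f"{prefix}fc.")

    def __call__(self, x, prior=None):
        """x: (M, F, H, W) masked features; prior: (M, C) binary or None."""
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if i in self.pool_after:
                x = ad.maxpool2(ad.pad2d_to_even(x))
        x = ad.global_maxpool(x)
        if self.use_prior:
            if prior is None:
                raise ValueError("use_prior model requires a prior vector")
            x = ad.concat([x, Tensor(np.asarray(prior, np.float32))], axis=1)
            return self.fc2(ad.relu(self.fc1(x)))
        return self.fc(x)


# ---------------------------------------------------------------------- model
class Model(Module):
    def __init__(self, config: ModelConfig):
        if config.variant not in VARIANTS:
            raise ValueError(f"unknown variant {config.variant!r}")
        if config.preset not in _PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}")
        self.config = config
        preset = _PRESETS[config.preset]
        self.stride = 2 ** len(preset["stages"])
        rng = np.random.default_rng(config.init_seed)
        g = config.norm_groups
        self.encoder = Encoder(preset, rng, g)
        skip_chs = list(preset["stages"])
        bott = preset["stages"][-1]
        pplus1 = 2 if config.variant == "binary_seg" else config.n_parts + 1
        F = config.f_seg_channels

        if config.variant == "single_decoder":
            dec = tuple(2 * w for w in preset["dec"])
            self.seg_decoder = Decoder(bott, skip_chs, dec,
                                       2 * preset["final"], F, rng, g)
            self.cent_decoder = None
        else:
            self.seg_decoder = Decoder(bott, skip_chs, preset["dec"],
                                       preset["final"], F, rng, g)
            self.cent_decoder = Decoder(bott, skip_chs, preset["dec"],
                                        preset["final"],
                                        preset["cent_final"], rng, g)
        self.part_head = Conv2d(F, pplus1, 1, rng)
        cent_ch = F if config.variant == "single_decoder" else \
            preset["cent_final"]
        self.offset_head = Conv2d(cent_ch, 2, 1, rng)
        self.heatmap_head = Conv2d(cent_ch, 1, 1, rng)
        # bias the heatmap head toward the rare-positive prior so the focal
        # loss is not swamped by the negative sea in early epochs
        self.heatmap_head.bias.data[:] = -2.19
        # offsets span tens of pixels while features are O(1); a fixed output
        # gain keeps the regressed values (and their gradients) well scaled
        self.offset_scale = 4.0 * self.stride

        if config.variant == "semantic_type":
            self.type_decoder = Decoder(bott, skip_chs, preset["dec"],
                                        preset["final"], preset["final"],
                                        rng, g)
            self.type_head = Conv2d(preset["final"], config.n_classes + 1,
                                    1, rng)
            self.classifier = None
        else:
            self.type_decoder = None
            self.classifier = Classifier(config, rng)

    # ------------------------------------------------------------- batched API
    def forward_batch(self, x: Tensor, seg_only: bool = False) -> dict:
        """x: (N, 3, H, W) Tensor -> dict of Tensors (logits, not probs).

        ``seg_only`` skips the centroid/type branches (pretraining phase).
        """
        h, w = x.shape[2], x.shape[3]
        if h % self.stride or w % self.stride:
            raise ValueError(
                f"input {h}x{w} not divisible by encoder stride {self.stride}")
        bott, skips = self.encoder(x)
        f_seg = self.seg_decoder(bott, skips)
        out = {"f_seg": f_seg, "part_logits": self.part_head(f_seg)}
        if seg_only and self.cent_decoder is not None:
            return out
        cent = f_seg if self.cent_decoder is None else \
            self.cent_decoder(bott, skips)
        out["offsets"] = self.offset_head(cent) * self.offset_scale
        out["heatmap"] = ad.sigmoid(self.heatmap_head(cent))
        if self.type_decoder is not None:
            out["type_logits"] = self.type_head(self.type_decoder(bott, skips))
        return out

    def classify_batch(self, masked_fseg: Tensor, prior=None) -> Tensor:
        """Masked features (M, F, H, W) -> type logits (M, C)."""
        if self.classifier is None:
            raise ValueError("semantic_type variant has no instance classifier")
        return self.classifier(masked_fseg, prior)

    # ------------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.named_parameters()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            for name, p in model.named_parameters():
                p.data = data[name].astype(np.float32)
        return model

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(config: ModelConfig) -> Model:
    """Construct a model for the given preset/variant configuration."""
    return Model(config)


# ------------------------------------------------------------- per-frame API
def _to_nchw(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    return img.transpose(2, 0, 1)[None]


def _bundle(out: dict, k: int) -> PredictionBundle:
    part_logits = out["part_logits"].data[k].transpose(1, 2, 0)
    e = np.exp(part_logits - part_logits.max(axis=-1, keepdims=True))
    tl = out.get("type_logits")
    return PredictionBundle(
        part_logits=part_logits,
        part_probs=e / e.sum(axis=-1, keepdims=True),
        offsets=out["offsets"].data[k].transpose(1, 2, 0),
        heatmap=out["heatmap"].data[k, 0],
        f_seg=out["f_seg"].data[k].transpose(1, 2, 0),
        type_logits=None if tl is None else tl.data[k].transpose(1, 2, 0),
    )


def forward(model: Model, image: np.ndarray) -> PredictionBundle:
    """Run the network on one (H, W, 3) image and return numpy outputs."""
    with ad.no_grad():
        return _bundle(model.forward_batch(Tensor(_to_nchw(image))), 0)


def forward_many(model: Model, images, chunk: int = 8) -> list:
    """Forward a sequence of same-shape images in batches (inference only)."""
    bundles = []
    images = list(images)
    with ad.no_grad():
        for i in range(0, len(images), chunk):
            x = np.concatenate([_to_nchw(im) for im in images[i:i + chunk]])
            out = model.forward_batch(Tensor(x))
            bundles.extend(_bundle(out, k) for k in range(x.shape[0]))
    return bundles


def classify_instance(model: Model, f_seg: np.ndarray, mask: np.ndarray,
                      prior=None) -> np.ndarray:
    """Classify one instance from its masked feature map.

    f_seg: (H, W, F); mask: (H, W) boolean with at least one true pixel;
    prior: optional length-C binary presence vector (required iff the model
    was built with ``use_prior``).  Returns a length-C probability vector.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty instance")
    x = (np.asarray(f_seg, np.float32) * mask[..., None]).transpose(2, 0, 1)[None]
    pr = None if prior is None else np.asarray(prior, np.float32)[None]
    with ad.no_grad():
        logits = model.classify_batch(Tensor(x), pr).data[0]
    e = np.exp(logits - logits.max())
    return (e / e.sum()).astype(np.float32)
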
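# surgseg

Box-free multi-instance segmentation and classification of surgical
instruments in endoscopic images, built around a *mask-then-classify*
design: instrument instances are extracted pixel-wise first, and each
extracted instance is then classified independently from the features it
covers.

## The problem

Robotic-surgery video understanding needs to know, per pixel, *which*
instrument occupies it (the instance `i`) and *what kind* of instrument it
is (the type `c`), with `(0, 0)` reserved for background.  Semantic
segmentation struggles here for two structural reasons: instrument types
differ mainly at the small articulated tip (the clasper) while sharing
identical shafts and wrists, and instruments are elongated, spanning large
image fractions at arbitrary angles — so bounding-box detectors fare poorly
and pixel-local classifiers cannot see the evidence (the tip) needed to
label a distant shaft pixel.

## The method

A shared encoder feeds two light decoder heads:

* a **part segmentation** head `y_s` over {background, shaft, wrist,
  clasper, other}, trained with cross-entropy + soft DICE;
* a **centroid/offset** head producing a centroid heatmap `y_c` (Gaussian
  bumps at the per-instance median pixel, sigma = 20 at full training
  resolution, max-combined; trained with a penalty-reduced focal loss with
  alpha = 2, beta = 4) and per-pixel offsets `y_o(p) = p − c(i)` (masked L1).

At inference, heatmap peaks surviving a 3×3 non-maximum suppression (at
most 4 — up to three instruments plus an ultrasound probe) become instance
centroids, and every foreground pixel `p` (part argmax ≠ background) joins

    argmin_i ‖ p − y_o(p) − s_i ‖₂ .

Each instance mask `m_i` then gates the final segmentation feature map
`f_seg` (32 channels), and a shallow CNN classifies `f_seg · m_i` into one
of 7 instrument types — so the classifier sees exactly the pixels of one
instrument, wherever they lie.  Training minimizes

    L = L_type + L_offset + L_centroid + γ · L_seg,   γ = 10,

with the classifier teacher-forced on ground-truth instance masks, f_seg
perturbed by channel dropout, inverse-frequency class weights, instruments
without a visible clasper excluded from the classification loss, and
frames with no visible clasper discarded from training.  A binary
"instruments attached to the robot" presence vector can optionally be
concatenated to the classifier's pooled features (the kinematic prior).

Because no GPU-scale dataset ships with the package, a seeded synthetic
generator produces instrument-like scenes that reproduce the structural
premises above: elongated capsule shafts entering from the border at random
angles, identical shaft/wrist appearance across classes, class-specific tip
geometry only, overlap by draw order, and tips that may leave the frame.

## Worked example

```python
import numpy as np
from surgseg import (SynthConfig, generate_scenes, ModelConfig,
                     tiny_train_config, train, predict_frame, evaluate_model)

scenes = generate_scenes(SynthConfig(), 200, seed=1000)
held_out = generate_scenes(SynthConfig(), 50, seed=2000)
result = train(ModelConfig(preset="tiny", init_seed=1),
               tiny_train_config(seed=1), scenes)
report = evaluate_model(result.model, held_out)
print(f"foreground IoU {report.binary_iou:.3f}  "
      f"type accuracy {report.type_accuracy:.3f}  "
      f"types mIoU {report.types_miou:.3f}")
```

On one CPU this trains the tiny preset (stride-8 encoder, 64×80 scenes) in
a few minutes and prints held-out scores, e.g.

```
foreground IoU 0.980  type accuracy 0.293  types mIoU 0.156
```

i.e. the binary instrument mask overlaps ground truth at ~0.98 IoU, while
desk-scale instance *typing* — one of seven classes, from tip geometry
alone, since shafts and wrists are identical across classes — remains far
harder (see `docs/methods.md` for why ~0.3 is what 200 scenes and a
from-scratch stride-8 encoder buy).  The design comparisons are decisive at
this scale nonetheless: the same budget trained as a pixel-wise
semantic-type decoder reaches only ~0.08 types mIoU versus ~0.30 for
mask-then-classify, and supplying the kinematic presence prior lifts type
accuracy by ~0.13-0.18.

The same pipeline is scriptable from the shell:

```bash
surgseg synth --n-frames 200 --seed 0 --out data/train
surgseg train --manifest data/train/manifest.json --out runs/tiny
surgseg predict --manifest data/val/manifest.json \
    --checkpoint runs/tiny/checkpoint_last.npz --out preds/
surgseg evaluate --manifest data/val/manifest.json \
    --checkpoint runs/tiny/checkpoint_last.npz
```

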
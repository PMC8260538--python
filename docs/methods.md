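# Methods

This note documents the model, the training procedure, the synthetic data
the package ships with, and the numerical and design choices a maintainer
would want to know about.  Nothing here states a result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

A labeled frame carries an RGB image, an instance-id map (0 = background),
a part-label map over {background, shaft, wrist, clasper, other}, a
per-instance type in {1..7}, and a per-instance clasper-visibility flag.
The two maps must share the same foreground: a pixel has an instance id iff
it has a part label.  Coordinates are 0-based `(row, col)`, origin
top-left.  Ground-truth instance ids are arbitrary positive integers;
predicted ids are centroid ranks (1 = highest score), so outputs are
deterministic and score-ordered.

The paper-scale datasets never define when a clasper counts as "visible",
so the package uses a pixel-count threshold: an instance's clasper is
visible iff at least `min_pixels` (default 10) of its pixels carry the
clasper label.  The rule is monotone in the threshold and is re-derived
wherever geometry changes (synthetic rendering, crops).

## Targets

* **Centroid**: per-axis median of all visible pixels of the instance —
  including disconnected fragments of an occluded instrument — rounded
  half-away-from-zero to an integer pixel.  The median, not the mean, keeps
  the center on elongated bent shapes.
* **Heatmap**: unnormalized Gaussians at each centroid, combined by
  maximum, so the map is exactly 1 at centroid pixels (the focal loss's
  positive set is `y = 1`).  The Gaussian width is sigma = 20 px at full
  training resolution (512×640-class frames); the tiny preset scales it to
  sigma = 3 at 64×80, near the resolution ratio, so neighbouring bumps
  still separate.  Gaussians are evaluated densely (no truncation radius).
* **Offsets**: `y_o(p) = p − c(i)` at every foreground pixel, zero on
  background.  With this sign the grouping rule `p − y_o(p) = c(i)` holds
  exactly on ground truth, which the round-trip acceptance check exercises
  on 1,000 scenes.

## Losses

* Part segmentation: mean pixel-wise cross-entropy plus soft DICE (1 −
  mean over all P+1 classes of the smoothed overlap ratio, smoothing 1.0,
  computed per frame and averaged).  Probabilities are clamped at 1e−6
  before logs.
* Offsets: L1, averaged over foreground pixels per frame; frames without
  foreground contribute zero.
* Centroids: penalty-reduced focal loss with alpha = 2, beta = 4,
  normalized by the per-frame ground-truth instance count N (floor 1) —
  the convention of center-point detectors, since the loss's source leaves
  N undefined.
* Types: weighted cross-entropy per classified instance, averaged over the
  instances of the batch; weights are inverse per-instance type frequencies
  of the training split (counted over clasper-visible instances, since only
  those are classified), normalized to mean 1.
* Joint: `L_t + L_o + L_c + gamma * L_s` with gamma = 10, privileging mask
  quality.

## Architecture

A plain conv-norm-relu encoder (group normalization, 8 groups everywhere;
2×2 max-pool between stages) feeds two decoders; each decoder block is a
nearest-neighbour ×2 upsample followed by two conv-norm-relu layers, with
channel-concatenation skips from the last three encoder stages, and a final
three-layer conv block at input resolution.  The segmentation decoder's
final block outputs the 32-channel feature map `f_seg`, from which a 1×1
projection produces the part logits; the second decoder yields the offset
and heatmap heads (1×1; sigmoid on the heatmap).  The offset head carries a
fixed output gain of 4 × encoder stride: offsets span tens of pixels while
normalized features are O(1), and without the gain Adam cannot grow the
head's weights to the needed scale within the schedule.

Presets: `full` mirrors EfficientNet-B0 stage widths
(16/24/40/112/320, stride 32) with decoder widths 256/128/64/48/32;
`tiny` uses three stages (16/32/64, stride 8) and decoder widths 32/16/8,
sized so a full training run takes minutes on one CPU.  The heatmap head's
bias is initialized to −2.19 (a sigmoid prior of ~0.1), the standard
focal-loss initialization: without it the rare positive peaks are swamped
by the negative sea and never rise.

The instance classifier consumes `f_seg` multiplied by one instance mask
(all channels) and applies four conv-norm-relu layers with stride-2
max-pooling after the first and the last, then a global max-pool and a
fully connected layer over the 7 types.  The pooling placement is the one
genuinely open architectural question; pooling after every conv was tried
first and discards the tip geometry that defines the classes at small
scales (held-out type accuracy dropped to near chance in a frozen-feature
probe), so resolution is kept through the middle of the stack.  With the
kinematic presence prior enabled, the binary instruments-attached vector is
concatenated to the pooled feature and a second FC layer (hidden width 64)
produces the logits.

Ablation variants: `single_decoder` merges the two decoders into one with
doubled widths; `binary_seg` reduces the part head to
instrument-vs-background; `semantic_type` removes the classifier and adds a
third decoder predicting per-pixel type logits.

## Inference

Heatmap peaks are 3×3 local maxima above 0.1, capped at the 4 best (at
most three instruments plus an ultrasound probe appear at once); ties break
lexicographically by (row, col) so output is deterministic.  Foreground is
the part-head argmax (any non-background part).  Each foreground pixel
joins the nearest centroid of `p − y_o(p)` (ties to the smaller index);
instances below `min_instance_pixels` are dropped and ids renumbered in
score order.  An instance's detection score is its centroid score times its
maximum class probability.  Frames without centroids yield zero instances.

## Training schedule

Two phases: the encoder and segmentation decoder pretrain alone on the
segmentation loss, then the whole network trains end-to-end on the joint
loss with teacher forcing (classifier masks come from ground truth during
training, predictions at evaluation) and channel dropout 0.2 on `f_seg`.
Instruments without a visible clasper are excluded from the classification
loss; frames with no visible clasper at all are dropped from training
entirely (the literal reading — segmentation supervision on those frames is
forfeited too; `filter_classification_batch` is the single switch
implementing the rule).  Evaluation never filters.

The optimizer is AdamW (decoupled weight decay 0.01 applied to matrices
only).  Full preset: base lr 1e−3 dropped to 1e−4 after epoch 100, batch
24, 20-epoch pretrain, resize 512×640, random crop 384×480, flip/rotation/
photometric augmentation.

The tiny schedule (the desk-scale study: 30 epochs, 5 pretrain, batch 8,
base lr 3e−3) re-balances that recipe for training from scratch — there is
no ImageNet pretraining here — in three ways, each grounded in the
architecture's dependency structure:

* *per-branch learning rates*: the trunk (encoder + segmentation decoder)
  drops tenfold at epoch 12 so the `f_seg` features the classifier
  consumes stop drifting; the centroid/offset branch, which feeds nothing
  downstream, keeps the base rate until epoch 26; the classifier holds the
  base rate throughout.  The joint phase before the trunk breakpoint is
  essential — the type-loss gradient must shape `f_seg` while the trunk
  still learns, otherwise the features never become type-discriminative;
* *mixed cropping*: random 48×64 crops on half the batches (translation
  augmentation that measurably improves the dense heads) and full 64×80
  frames on the rest, where offset/centroid targets are unambiguous — a
  crop changes which pixels are visible and therefore moves the median
  centroid — and instrument tips are never cut.  A crop-truncated tip
  displays the geometry of a different class, so instances whose clasper
  the crop itself truncated are excluded from the classification loss for
  that sample;
* *no rotation augmentation*: at a 5–7 px tip scale, nearest-neighbour
  label rotation destroys the silhouettes that define the classes
  (measured as a large drop in classification accuracy); horizontal and
  vertical flips plus ±20% photometric jitter are kept.

The tiny schedule also caps the classification minibatch at 8 randomly
sampled teacher-forced instances per optimizer step (the number of
classifier updates per epoch is unchanged); classifying every instance of
every batch at full resolution would dominate the step cost without
improving convergence.

Both the best-by-validation and the final checkpoints are saved when a
validation split is given, since validation-selected scores are optimistic.

## Synthetic scenes

The generator reproduces the structural premises that make this problem
hard, not the photometry of endoscopy:

* each instrument is anchored at its working tip — sampled in a slightly
  expanded frame so most tips are visible but some fall outside (hidden
  clasper) — with a capsule shaft running backwards through an image border
  at a random angle, a short wrist, and a class-specific tip template
  (disc, fenestrated ring, open-scissors vee, solid jaw, cross-axis tee,
  cross, twin lobes).  Templates differ in coarse silhouette, are symmetric
  about the tool axis (so flips map classes to themselves) and are centered
  on the anchor; an earlier template set with sub-2-px prongs was not
  pairwise distinguishable once rendered, which violates both the
  generator's distinctness invariant and the premise that the clasper
  identifies the type;
* shaft and wrist appearance is identical across classes; *only* the tip
  geometry identifies the type, so pixel-local classification cannot solve
  the task — the premise behind the mask-then-classify design;
* instruments overlap by draw order; an occluded instrument keeps one id
  across disconnected fragments;
* intensities: background 0.25 with flat/noise/blob texture, shaft 0.70,
  wrist 0.80, clasper 0.92, small pixel noise, identical across classes.

Per-scene instrument counts are uniform on 0..4 (the inference cap).  What
passing tests on these scenes shows: the grouping machinery, losses,
protocol scoring, and the architecture's ability to recover instances and
types from tip geometry alone at desk scale.  What they do not show:
robustness to specular highlights, smoke, blood, motion blur, real tissue
backgrounds, or video correlation — no claim about EndoVis-scale accuracy
is made or testable here.

## Numerical choices and degenerate inputs

Probabilities are clamped to [1e−6, 1−1e−6] before logs; the focal loss's
positive set is exact equality `y = 1` (centroids are placed at integer
pixels precisely so this set is well defined); empty foreground returns 0
offset loss; empty centroid lists yield zero-instance results and a logged
warning; `classify_instance` refuses empty masks (callers drop
sub-threshold instances first); group counts divide channel counts by
construction, and group normalization falls back to fewer groups when a
width is not divisible by 8.  All computation is float32; training is
bit-deterministic for a fixed seed (numpy RNGs only, no threading
nondeterminism).

## Problem sizes used by the shipped studies

The reference study trains the tiny preset on 200 synthetic 64×80 scenes
for 30 epochs and evaluates on 50 held-out scenes.  The directional
comparisons (classifier vs semantic-type decoder, presence prior vs none)
train their arms on the *same* 200 scenes with the same seed and schedule,
the reference model serving as the proposed/no-prior arm — shorter arm
budgets were tried first and measure optimizer warm-up rather than the
design difference, because the instance classifier only converges once the
segmentation features settle.  The ground-truth round-trip check runs on
1,000 scenes.

## Known limitations

* Desk-scale instance typing is the binding constraint of the tiny study.
  The classifier's held-out ceiling on `f_seg` features at this data size
  (~380 training instances) is about 0.7 even on ground-truth masks, and
  imperfect predicted masks — offsets from a stride-8 from-scratch encoder
  carry several pixels of error, so masks leak pixels of neighbouring
  instruments into the global max-pool — cost a further ~0.2.  Held-out
  per-instance type accuracy therefore lands far below what full-scale
  training (ImageNet-pretrained encoder, ~1300 real frames) reaches; the
  directional findings are unaffected and decisive.
* The mask mAP of the tiny desk-scale model is low in absolute terms:
  instance masks inherit every foreground pixel the part head labels, and
  at 64×80 the strict high-IoU thresholds punish single-pixel boundary
  errors heavily.  The metric is reported for completeness and used for
  relative comparisons only.
* The semantic-type ablation shares the tiny trunk; its absolute scores,
  like all tiny-preset scores, are not comparable to full-resolution
  training on real data.
* The EndoVis directory reader is a best-effort adapter and is not
  exercised by the test suite (external data).
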
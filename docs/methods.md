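# Methods

`marrowdet` implements a single-stage, anchor-based detector for bone-marrow
(BM) cells in Wright-stained aspirate-smear images. The architecture is the
YOLOv7 lead-head layout with two backbone modifications aimed at small,
visually similar, densely packed cells — a contextual-transformer final stage
inside each aggregation block (CoTLAN) and coordinate attention (CoordAtt)
after each downsampling stage — plus IoU-k-means++ anchor priors, a focal
classification loss, CIoU localization, and CIoU-based NMS.

## Numerical core

The detector runs on a small reverse-mode autodiff engine over NumPy
(`marrowdet.autograd`): a float32 `Tensor` with the primitives a
convolutional detector needs (convolution as strided GEMMs over kernel
offsets, max-pooling, batch norm composed from elementwise/mean primitives,
SiLU/hard-swish/sigmoid, indexing, concatenation, nearest upsampling). All
gradients are checked against central differences in the test-suite. The
optimizer is momentum SGD with per-group weight decay (conv weights only).
This keeps the package dependency-light and fully deterministic given a seed;
the cost is speed, which the desk-scale defaults below account for.

Batch-norm uses eps 1e-3 and EMA momentum 0.03 (detector convention,
config-exposed). Running statistics are warm-started from the first training
batch: with an EMA from the (0, 1) init, a ~50-block network multiplies a
per-layer scale error into astronomically wrong eval-mode activations until
the EMA converges, so the first batch defines the starting statistics and
the EMA takes over afterwards.

## Architecture

Backbone: four CBS stem convs (two stride-2), then four aggregation blocks
with downsampling (MP) between them; strides 8/16/32 feed the neck. The
channel plan is the YOLOv7 one (stem 32-64-64-128; block hidden widths
64/128/256/256; block outputs 256/512/1024/1024). Neck: SPPCSP (1024 -> 512,
pyramid windows 5/9/13 realized as three cascaded stride-1 5x5 pools),
top-down FPN and bottom-up PAN with six-tap aggregation blocks. Head: one
re-parameterizable RepC 3x3 per level (fusable to a single conv for
deployment) and a 1x1 conv to 3*(5+C) channels.

* CoTLAN replaces the last 3x3 conv of each backbone aggregation block with
  a contextual-transformer block: a static context K1 (3x3 group conv,
  groups 4) summed with a dynamic context K2 obtained by re-weighting each
  3x3 neighborhood of a 1x1 value embedding with per-head attention computed
  from [K1, input]. Heads = max(C/64, 1); the attention bottleneck reduces
  2C by a factor of 4 (the contextual-transformer source convention, which
  also lands the parameter budget at the published ~36.0 M; factor 2 would
  give a smaller saving). The K1/K2 fusion is an elementwise sum — the
  simplest fusion; the gated fusion of the original contextual-transformer
  design is deliberately out of scope.
* CoordAtt (reduction 32, minimum 8 bottleneck channels, hard-swish) is
  inserted once after each backbone MP block — three insertions, which is
  where "after the downsampling stages" and "between consecutive aggregation
  blocks" coincide in this cadence.
* With both toggles off the graph is the plain CBS+ELAN YOLOv7 baseline
  (36.6 M parameters at 15 classes, deployed); with them on, 36.0 M — the
  CoT blocks save more than the attention adds.

Parameter counts are reported for deployed (RepC-fused) graphs, matching how
single-stage detector sizes are conventionally quoted; the training graph
carries the extra 1x1/identity branches.

Input resolution defaults to 640 (divisible by 32; the deepest map is then
20x20). `width_scale` shrinks all internal channel counts (multiples of 8,
minimum 8) for CPU-scale experiments; it does not change the topology.

## Anchors

Ground-truth (w, h) pairs — positions ignored — are clustered with
k-means++ under D(x) = 1 - IoU(x, c), seeding by squared-distance roulette
P(x) = D^2/sum D^2, Lloyd updates by per-cluster arithmetic means, stopping
when assignments are stable (max 300 iterations). Ten seedings are run and
the lowest total within-cluster distance wins (Lloyd is a local search; a
single seeding can merge well-separated size clusters). Boxes are sorted
before seeding so results do not depend on input order. The nine anchors are
split by area across strides 32/16/8 (ties by width, then height) and
clustered in network-input pixels. Defaults are the published priors for the
BM-cell data (38x39 ... 74x75 at 640).

## Losses and target assignment

Total loss (weights config-exposed): `w1*box + w2*cls + w3*obj` with
defaults 0.05/0.3/0.7 (YOLO convention; the weights are not specified by the
source method).

* Classification: one-vs-all sigmoid focal loss, alpha 0.25, gamma 2
  (focal-loss source defaults), mean over positives.
* Localization: 1 - CIoU between decoded boxes at positive assignments and
  their ground truth, in grid units; the aspect-term coefficient alpha_v is
  excluded from gradients (standard CIoU practice).
* Objectness: BCE over the full map per level with level balance 4/1/0.4
  (fine to coarse); the positive target is 1 - g + g*CIoU of the matched
  prediction (IoU-aware soft label with gain ``obj_gain`` = g, default 1;
  config flag ``soft_obj`` switches to the hard label 1).

Assignment: a gt matches an anchor when both w and h ratios lie in
[1/4, 4]; positives are written at the gt's cell plus the two nearest
neighbor cells (0.5-offset rule). When several gts claim the same (image,
anchor, cell) slot — frequent for crowded, same-sized objects on coarse
grids, where it otherwise puts an irreducible floor under the box loss by
giving one prediction contradictory targets — the slot keeps the gt with
the best anchor wh-ratio fit. The slot set of positives is unchanged by
this rule; only the regression/class target at contested slots becomes
unique. Decode: center (2s(t)-0.5+grid)*stride, size (2s(t))^2*anchor,
score obj*cls.

## NMS

Candidates above the confidence threshold are walked in descending score;
a candidate is suppressed when its CIoU *similarity* with a kept same-class
box exceeds the threshold (defaults 0.25 / 0.45, max 300 detections). The
procedure description this implements speaks of removing boxes whose CIoU
*loss* exceeds the threshold; read literally that deletes non-overlapping
boxes and inverts the operation, so it is treated as a wording slip and the
standard suppression direction is used.

## Evaluation

Greedy matching at IoU 0.5: detections in canonical order (descending score,
ties by box coordinates then class — this makes mAP invariant to input
order), each gt consumed at most once, same class only. AP is the area under
the monotone-envelope PR curve (all-points interpolation, the YOLO-lineage
convention rather than 11-point); mAP@0.5 averages classes present in the
ground truth. With zero detections precision is defined as 1.0.

## Synthetic smears

The generator emulates the source dataset's statistics so the full pipeline
is testable without the real data: 600x600 tiles, ~11 cells/image
(Poisson; 13,059 cells over 1,204 images), box side fractions from a
truncated normal (mean 0.09, sd 0.02, bounds [0.03, 0.25]) matching the
"about 9% of the image size" label statistics, and a long-tailed class
distribution over 15 BM cell types. Cells are rotated cytoplasm ellipses
with darker nuclei on a textured pink background; classes differ in hue,
nucleus-to-cell ratio and eccentricity so they are learnable. Placement
allows pairwise box IoU up to 0.3 (dense, touching cells); a cell that
cannot be placed in 50 attempts is skipped. What this does *not* model:
real Wright-stain morphology (lobed nuclei, granules, smudge artifacts),
staining variation, focus blur, and inter-class similarity structure —
passing end-to-end tests demonstrates that the pipeline learns and measures
correctly, not that it reaches any particular accuracy on real smears.

## Desk-scale problem sizes and the overfit smoke

Full-width training at 640 is a GPU-class workload and is out of scope here;
the package's own experiments use width_scale 0.125 models (~0.6 M
parameters) at 96-224 px inputs and a few hundred optimizer steps. The
overfit smoke in the test-suite trains on 16 synthetic images for 200
epochs (800 SGD steps at batch 4) and checks that the training loss
collapses below 10% of its initial value and that the memorized images are
re-detected at mAP@0.5 — a pipeline-correctness check, not an accuracy
claim.

The smoke configuration differs from the library defaults in three
documented ways, all parameters the source method leaves unspecified:
loss weights (0.5, 2.0, 0.7) instead of (0.05, 0.3, 0.7) — at 800 steps the
YOLO-convention weights leave classification at chance-level accuracy while
objectness saturates (a gradient-balance effect: the classification-only
ablation converges to 100% accuracy); hard objectness labels — the
IoU-aware soft label carries an entropy floor that dominates the total loss
at desk-scale positive densities (~13% of the fine map vs ~1% at the
published scale); and focal alpha 0.75 — alpha corrects class imbalance,
and with 15 sigmoid outputs the positive:negative ratio is 1:14, so
down-weighting positives (0.25, the 1:1000 anchor-imbalance convention)
points the correction the wrong way. Training uses a cosine schedule from
lr 0.15 with a 6-epoch warmup and a weight EMA (decay 0.995, ramped in)
whose average is the deployed/evaluated model.

## Degenerate inputs and tie-breaks

Ground-truth boxes with non-positive size are skipped with a warning.
Empty k-means clusters are re-seeded from the farthest box. Probabilities
are clamped at 1e-7 before logs. Detection ties at equal score break by box
coordinates; anchor-area ties by width then height. Mosaic boxes losing more
than 90% of their area to clipping are dropped. Letterbox padding value is
114; boxes are half-open pixel intervals in 0-based coordinates.
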
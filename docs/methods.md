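# Methods

## Problem and model

Three horsetail taxa are told apart by the appearance of nodal leaf
sheaths along pressed aerial stems: *Equisetum hyemale* sheaths are
cross-banded (dark basal stripe, pale tan band, dark rim), *E. laevigatum*
sheaths are green with a narrow black rim, and the sterile hybrid
*E. ×ferrissii* mixes the two appearances with hyemale-like sheaths
predominating basally and laevigatum-like sheaths apically. The pipeline
has two stages: a detector that localizes stem nodes and types each one as
H or L (optionally F), and an image-level classifier over aggregate
detection statistics.

Node types are **proxy labels**: the detector is never told what an H
sheath looks like; it is trained on boxes from verified *E. hyemale* and
*E. laevigatum* images, every node inheriting its image's taxon. The
hybrid hypothesis — that *×ferrissii* nodes individually resemble one
parent or the other rather than having their own appearance — is what
makes the two-type detector informative about a taxon it never saw in
training.

## Detector

The detector is anchor-based and single-stage. Grid points are placed
every `pitch` = 30 px (the smallest node size of interest); each point
carries 36 anchors, the cross product of six sizes (geometric progression
30–120 px) and six width/height ratios (1/3 … 2). Training targets follow
the usual single-shot assignment: an anchor is positive for a ground-truth
box when their IoU ≥ 0.5 (and each ground-truth box always claims its
best-IoU anchor); positives get center/size offset targets
((Δcx/w, Δcy/h, log w-ratio, log h-ratio)).

The scoring model is deliberately compact so training runs in minutes on
one CPU core. Each anchor is described by integral-image pooled color
features: a 3×3 grid of per-cell RGB means (27), a 6-band top-to-bottom
RGB profile (18), and log box dimensions (2). The 6-band vertical profile
is what separates the dark/light/dark banding of H sheaths from the green
field plus single rim of L sheaths; the 3×3 grid additionally encodes
where a node sits inside a loosely placed box, which is what the offset
head needs. A one-hidden-layer network (64 ReLU units) maps standardized
features to class logits ({background} ∪ type set) and four offsets.

Training minimizes softmax cross-entropy plus smooth-L1 offset regression
on positives (localization weight 2.0), normalized by the positive count,
with hard-negative mining at 3 negatives per positive. Mini-batches hold 8
augmented crops; optimization is Adam. Two negative pools are stored per
crop: anchors loosely overlapping a node (best IoU in [0.15, 0.4)) are
kept wholesale as hard negatives — without them the detector hallucinates
confident off-node detections along stems — and a random sample of far
negatives; anchors in the ambiguous band [0.4, 0.5) are ignored.

Key training defaults: batch size 8; up to 2000 iterations with a
validation error check every 50 and early stop after 5 checks without
improvement (best-validation checkpoint returned); 4 augmented crops per
training image; learning rate 1e-3. The learning rate deserves a note:
fine-tuning a large pretrained backbone conventionally uses 1e-4, but this
detector trains a small network from scratch on standardized pooled
features, where 1e-4 with Adam is visibly under-converged within the
iteration budget (validation error ~0.10 vs ~0.035 at 1e-3 in smoke
tests). 1e-4 remains available through configuration.

Inference scores every anchor on the whole image, takes the per-anchor
argmax over type classes (score = that softmax probability), drops scores
below 0.3, decodes offsets, and applies greedy non-maximum suppression:
detections are visited by descending score (ties: lexicographically
smaller box first) and kept iff IoU with every kept detection is ≤ the
overlap threshold. The NMS threshold defaults to **0.3** rather than the
conventional 0.5: pooled color features localize loosely, so duplicate
boxes around one node typically overlap at IoU 0.3–0.5, while distinct
nodes sit ≥ 1.5 node-heights apart and cannot be merged at 0.3. Both
thresholds are configurable and echoed in every report.

## Detection statistics

Per image and node type, detections are sorted by score and the top 10 are
averaged: a_H, a_L (and a_F in three-type mode). Fewer than 10 detections:
the average is over what exists; none: 0 with a recorded count of 0, so
"no evidence of the type" stays inside the bounded feature space. A
zero-padding variant (divide by exactly k) is available behind a flag for
sensitivity analysis, as are the ratio a_H/a_L (NaN sentinel when a_L = 0)
and top-k standard deviations; the means are the default because they
carry the cleanest signal. Score quantization to the 0–10 integer scale
(×10, round half away from zero) exists for display only and never feeds
computation.

## Classifiers

All three classifiers consume the unscaled feature vector (components
already share the [0, 1] range):

- **logistic** — multinomial logistic regression with mild L2 (C = 10);
  unregularized fits need not converge on separable 50-point datasets.
- **tree** — Gini impurity, max depth 3, minimum leaf size 2; tiny
  training sets demand strong regularization. Serialized as explicit node
  arrays; prediction is a plain threshold walk.
- **knn** — Euclidean 5-nearest-neighbor, majority vote; vote ties break
  to the class with the smallest mean neighbor distance, then to fixed
  taxon order (hyemale, laevigatum, ferrissii). Implemented directly
  because the tie rule is part of the contract.

Model selection on synthetic data uses seeded stratified k-fold
cross-validation over a small grid (logistic, tree, knn at several k).
The pipeline defaults mirror the two experiments: 5-nn on (a_H, a_L) in
two-type mode, the decision tree on (a_H, a_L, a_F) in three-type mode.

## Evaluation

Detections match annotations greedily: by descending score, each
detection claims the unmatched annotation of highest IoU, if that IoU
clears the matching threshold (default 0.5, echoed in reports). Matched
pairs feed the node-type confusion matrix (true proxy type × detected
type); its trace/total is the cross-type accuracy. The pairwise confusion
rate between two types restricts the matrix to rows and columns of that
pair and reports the off-diagonal fraction. Image-level predictions feed
the 3×3 taxon matrix and its accuracy. Percentages round half away from
zero, matching display convention. False-positive/negative counts are
computed but flagged advisory: manual annotation of herbarium sheets is
systematically incomplete, so unmatched detections are frequently genuine
nodes, and false-negative rates are not meaningful without exhaustive
annotation. In two-type mode, hybrid images have no defined true node
type and are excluded from the node matrix (attempting to include one
raises an error).

## Synthetic specimens

The generator draws 700×700 paper-colored sheets (gentle vertical lighting
gradient, Gaussian pixel noise σ = 4), 1–3 slightly leaning/bowed green
stems, and 6–12 nodes per stem at regular intervals (capped so nodes stay
≥ 1.5 node-heights apart — with the default 36 px node size that is at
most 11 per stem, i.e. roughly 6–22 nodes per image, matching the density
of annotated nodes on real sheets). H sheaths render as a dark/tan/dark
band triplet, L sheaths as a green field with a thin black rim; band
widths, hue, node size (±25%), and placement jitter per node. Hybrid
node types are drawn from a linear probability ramp between p_base = 0.9
(H at the stem base) and p_apex = 0.1, a configuration choice — the real
H:L ratio along *×ferrissii* stems is not quantified — with a logistic
ramp available. All randomness flows from one seeded generator per call;
outputs are bit-reproducible and include VIA v2 JSON plus a manifest CSV.

What the generator does **not** emulate: overlapping or crossing stems,
internode texture variation, injured nodes, strobili by default (they can
be rendered but are never detected), faded or discolored specimens, sheet
labels/barcodes, and the full resolution of digitized sheets. Passing
tests on synthetic data therefore demonstrate that the pipeline's
machinery — proxy labeling, anchor assignment, aggregation, classification
— is correct and recovers a planted base-to-apex gradient; they do not
certify accuracy on real herbarium images, where appearance variation is
far richer.

## Augmentation

Training crops are produced by rotating the image by a uniform random
angle about its center (border fill: mean image color, avoiding dark
wedges that would read as spurious features) and cutting a random 500×500
window. Rotated boxes become the axis-aligned hull of their four rotated
corners — the standard convention for axis-aligned detectors, which grows
boxes slightly at oblique angles. Boxes retaining less than half their
area in the crop are dropped (min_box_visibility = 0.5, configurable);
survivors are clipped. Images smaller than the crop are reflection-padded.
Evaluation images are processed whole, not cropped; anchor features are
resolution-independent, so the train/test size mismatch is benign for the
feature family used here.

## Numerical and degenerate-input choices

- Boxes are 0-based, half-open, float until rasterization; VIA's
  (x, y, w, h) converts losslessly to (x, y, x+w, y+h).
- NMS and matching tie-breaks are lexicographic on box coordinates after
  score, making both order-independent.
- Offset decoding clamps log size deltas to ±4 to keep degenerate
  regressions finite; boxes thinner than 1 px after decoding are dropped.
- An empty detection list yields all-zero statistics, which classifiers
  handle like any other point; an empty confusion matrix raises rather
  than returning 0/0.
- Dataset splits are stratified by taxon with floor allocation per group
  and seeded assignment of remainders, so the published 54/24/30 design on
  36+36+36 images yields exactly 18/8/10 per taxon.

## Problem sizes

Default experiment scale is 36 synthetic images per taxon (108 total,
54/24/30 split), the two-type detector training on the 36 pure-species
train images. One full pipeline run at these sizes takes on the order of
a minute per mode on a single CPU core; the replication tests run this at
three seeds, and unit tests use smaller images (150–320 px) and shorter
training schedules.

## Known limitations

- The detector's pooled-color features are tuned to the banding/color
  contrast and would not transfer to structures distinguished by texture
  or fine shape; the architecture is a contract-compatible desk-scale
  stand-in for a deep single-shot detector, not a substitute for one at
  archive scale.
- Localization is loose (duplicate suppression relies on the 0.3 NMS
  threshold); box quality is adequate for score aggregation, not for
  morphometry.
- The per-specimen basal-vs-apical H-fraction comparison is noisy at
  realistic node counts: with ~6–22 nodes split into halves, binomial
  sampling alone makes the ordering fail in roughly one specimen in
  eight even when node types are read from ground truth. Aggregate
  (across-specimen) ordering is robust and is what the tests assert of
  the generator; the detector recovers the per-specimen ordering about as
  often as the ground truth itself allows (~91% vs ~88% in 200-specimen
  runs).
- Three-type mode exhibits heavy H↔F node confusion by construction —
  hybrid nodes *are* H- or L-looking — mirroring the biological situation;
  its image-level accuracy is nevertheless comparable to two-type mode.
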
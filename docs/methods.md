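# Methods

This note documents the models, procedures and design decisions behind
vineprep, in the order data flows through the pipeline.

## Synthetic leaf model

The synthetic generator stands in for non-public field collections of six
red grape varieties (a few tens of images per variety at camera resolution).
It is not a renderer; it produces the minimal structure the pipeline needs to
be exercised honestly:

* **Silhouette** — the union of `lobe_count` ellipses rotated evenly around a
  jittered center.  The base radius is adjusted iteratively (deterministic,
  ≤ 12 steps) until foreground coverage lands in the 10–70% band, which the
  sample contract guarantees.
* **Veins** — parallel dark anti-aliased strokes at the class's
  `vein_angle_deg`, widened by binary dilation to `vein_width_px` and clipped
  to the silhouette.  The six default classes differ pairwise in lobe count
  and/or vein angle (angles 0°–150° in 30° steps), and additionally in leaf
  hue, emulating varieties that are similar but separable.  The
  `mean_vein_orientation` diagnostic (structure-tensor average of doubled
  gradient angles) recovers the class angle to within a couple of degrees and
  serves as the one-feature reference classifier.
* **Background** — a low-frequency color field plus random bright/dark blobs
  and pixel noise.  The green channel is clamped to 0.85 × max(R, B) at the
  end, so backgrounds are cluttered but never green-dominant; this keeps the
  chromatic segmentation cue realistic (leaves are the green thing in frame)
  while forcing the segmenter to reject structured clutter.

Every sample is a pure function of `(params, height, width, seed)`; dataset
generation derives per-sample seeds deterministically (kept below 2³¹).

What passing tests on this data do *not* show: robustness to occlusion,
specular highlights, senescence, disease, or green-on-green clutter in real
canopies.  The generator's role is to verify the machinery's contracts and
that the learning signal survives each transform, not to predict field
accuracy.

## Segmentation stand-in

Downstream operations rely on exactly one property of a segmented image:
background pixels are exactly (0,0,0) and everything non-black is leaf.  The
full leaf-segmentation algorithm this contract originates from belongs to
prior work and is not restated here; `segment_leaf` is a documented stand-in:
HSV green-band thresholding (hue 0.16–0.50, saturation > 0.15, value > 0.08,
G strictly dominant in RGB), binary opening (disk 2) to drop speckle, closing
(disk 5), hole filling, then the largest connected component.  On the
synthetic data it reaches IoU ≳ 0.99 against ground truth; the test contract
asserts ≥ 0.7.  A true-black foreground pixel would be indistinguishable
from background, so masking nudges (0,0,0) foreground to (1,1,1) first.
Inputs that already honor the contract pass through unchanged (idempotence).
Leaf-patch extraction tiles a grid anchored at the top-left pixel (no sliding
search — "non-overlapping" fixes no anchor, so the simplest one is used) and
keeps only tiles with zero black pixels.

## Four-corners-in-one warp

Compaction performs exactly one horizontal pass (each row's non-black pixels
shifted, order preserved, to the corner's side) followed by one vertical
pass.  One pass of each is already a fixed point of the per-row/per-column
rule, so no iteration is needed.  The four compacted images are rotated 180°
and tiled into full-size quadrants of a (2H+1)×(2W+1) canvas around a
one-pixel white cross; full quadrants lose no pixels.  Extraction grows the
half-side `s` while the 2s×2s square centered on the cross (cross row/column
excluded) is entirely non-black, then removes the cross, so the output side
is even.

Two readings of "largest square patch with non-black pixels inside" exist;
the dense reading (all pixels non-black) is implemented because the
permissive one (at least one non-black pixel) degenerates to the whole
canvas.  The operation invents no pixel values and is resolution-agnostic;
resizing to a network input size is the dataset recipe's job.  Errors: an
all-black input, or any quadrant without foreground touching the center,
raises `NoForegroundError`.

## Vein extraction

The morphology pipeline computes `g = (closing − f) − (f − opening)
= closing + opening − 2f` with a flat square structuring element (default
width 7, odd widths only) in signed 32-bit arithmetic, then clips to
[0, 255].  Clipping (rather than renormalizing) preserves the semantics that
only dark-structure (positive bot-hat) responses matter; this also makes the
response invariant to adding a constant and translation-equivariant in the
interior.  Borders use reflect padding to avoid artificial responses at
patch edges.  The Canny pipeline converts to luminance gray (ITU-R 601
weights), detects edges at σ = 1.75, zeroes all 8-connected components of
size exactly one, and replicates the binary map onto three channels.

## ICF bank

Patches are scanned row-major and vectorized row-major into a `p² × n`
matrix.  FastICA runs in parallel fixed-point mode with the cube contrast
(kurtosis-style), seeded, with columns as samples; non-convergence
(rank-deficient or Gaussian-only input, on which ICA is unidentifiable) is
surfaced as `IcaConvergenceError`.  Filter rows are normalized to unit norm;
the whitened-space rotation is retained for orthogonality diagnostics
(pairwise orthogonal within 1e-6).

The canonical selection rule ("randomly selected … the first three, last
three, and the remaining 19 uniformly spaced using a gap of three") is
self-contradictory; the deterministic reading wins for reproducibility:
first three rows, last three rows, and `k − 6` interior rows by rounded
linear spacing over the interior.  A literal gap-of-3 arithmetic mode
(rows 4, 7, 10, …) is provided as an alternative; for a 64-filter bank it
nearly spans the interior, for 144 it does not.  Convolution uses reflect
boundaries and same-size outputs with per-image min–max rescaling to 8-bit
(both unspecified in the source description).  Block selection cuts a
deterministic r×c grid (r·c = count, larger grid dimension on the longer
image axis) with rounded-linear-spaced positions; which positions the
original authors used is unknowable, so the evenly spaced grid is the
package's choice.

One printed matrix size in the patch-based ICF pathway (64 rows × 3,644
columns) is dimensionally inconsistent with its own construction (3,644
patches each contributing 64 blocks); the builder uses 64 × (3,644 × 64) by
construction and treats the printed figure as an erratum.  Relatedly, the
patch-based ICF recipe is count-preserving (one output per patch, convolved
with the first selected filter), because its canonical dataset total equals
patches × F25 with no 25-fold filter expansion — unlike the whole-image ICF
recipe, whose total does include the 25 × 8 filter-block expansion.

## Augmentation arithmetic

Translation resizes (bilinear) to `S = crop + √F − 1` and enumerates all
`(√F)²` one-pixel-shifted windows row-major — enumeration, not sampling,
because only enumeration reproduces the canonical totals deterministically.
The mirror method is a horizontal reflection (its own name; the alternative
description as a 180° rotation is a different transform and is not used).
Rotation produces the ten angles −5…−1, +1…+5 with bilinear interpolation
and black fill at constant output size.

## Recipes, splits and counts

Counts compose as: translation contributes `n·F`; mirror duplicates the
translated set; rotation multiplies translated + mirrored by ten and never
touches the retained originals (only that composition reproduces the
canonical 328,000 and 120,000 rotation rows); recipes #8–#10 retain raw
originals.  The mirror branch of recipe #9 is implemented as mirror-each-crop
(count-equivalent to mirroring raws before cropping, and streaming-friendly).
Splits are taken per class at the raw-image level before any augmentation —
six test images per class with the remainder shuffled 80/20, or ten test
plus six validation per class (224 → 128/36/60) — so leakage across splits
is structurally impossible, which the manifest tests assert.  Test images
are augmented with the same recipe as training images, and evaluation can
report both per-crop accuracy and per-raw-image majority vote, since
test-time aggregation is otherwise unspecified.

`expected_counts` is the closed-form audit; `build_dataset` is the
record-level builder.  Their equality is asserted on synthetic collections
(n = 6 and 12 raws per recipe; one scaled recipe — crop 32, F25 — is
materialized to PNG end to end).  Full-scale builds (126,000+ images) are
enumerated as manifests without materializing pixels.

## Transfer-learning harness

The backbone is constructed from a declarative layer table rather than
hard-coded, so the full 25-row reference architecture is dimension-verified
(every printed width/height/depth and the 9216-unit fc6 input follow from
`out = ⌊(in + 2p − k)/s⌋ + 1` and flattening) while training runs on a
reduced table with the same layer kinds (three convolutions, cross-channel
normalization, overlapping pooling, an fc6-analogue feature layer) at 32×32
input.  The network itself is a compact numpy implementation with exact
backpropagation (verified against finite differences for every trainable
layer, including through the local response normalization); convolution uses
im2col over NHWC arrays.

Transfer schemes set per-layer learning-rate multipliers: retrain-everything;
freeze the first two convolutional layers (multiplier zero — frozen layers
are skipped entirely by the optimizer and stay bit-identical); or freeze all
and expose fc6 activations to a multiclass linear SVM with stratified k-fold
cross-validation and a grid search over C (default grid 10⁻³…10³, the grid
being otherwise unspecified).  The optimizer is SGD with classical momentum
and L2 weight decay; full-scale defaults follow the canonical setting
(lr 1e-5, momentum 0.9, weight decay 1e-1, batch 32, patience 10 validation
points at one validation per epoch).  Desk-scale runs use lr 0.02 and weight
decay 1e-4, since the full-scale values presuppose pretrained weights and
10⁵-image epochs.  Early stopping halts when the validation loss has failed
to improve for `patience` consecutive validation points; one weight
checkpoint is kept per completed epoch.

Pretrained weights are an optional user-supplied file (shape-checked on
load); nothing in the package or its tests depends on them.

## Problem sizes

Tests and the acceptance script run at desk scale by design: synthetic
images 96–256 px, 50–120 samples for statistical checks, warped inputs
downscaled to 32×32 for training, 120 samples (20 per class) for the smoke
experiment, brute-force oracles on ≤ 16×16 (warping, 200 trials) and 32×32
(morphology, 50 trials) arrays, and ICA recovery on 4–9 sources × 5–6k
samples.  The field-scale headline accuracies (77.30% in-field, 89.75% on the
public white-background benchmark) are not reproduction targets: they
require the non-deposited field images, an external benchmark download and
pretrained weights.  The smoke experiment checks the qualitative claims
instead — warped input trains far above chance, and does not underperform
plain resizing beyond noise on the same synthetic task.

## Known limitations

* The segmentation stand-in is a chromatic heuristic; it will fail on
  green-dominant backgrounds and is not a reimplementation of the original
  leaf-segmentation algorithm.
* The numpy CNN is single-threaded and desk-scale by intent; it is not a
  vehicle for full-resolution (227×227) training runs.
* The effective iteration budget behind the full-scale per-epoch accuracy
  tables cannot be inferred from the source description, so no attempt is
  made to mimic their epoch counts.
* Synthetic classes carry a deliberately clean vein/hue signal; accuracy
  numbers on them say nothing quantitative about field data.
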
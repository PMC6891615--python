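# vineprep

Image pre-processing, data augmentation and a desk-scale transfer-learning
harness for identifying grape varieties from field photographs of vine
canopies.

## The problem

Vineyards in regions such as the Douro frequently mix several visually
similar red grape varieties within one parcel, and identifying the variety
from a natural (in-field, cluttered-background) leaf photograph is hard even
for experts.  Classification pipelines for this task lean heavily on
pre-processing: segmenting the leaf onto an exact-black background,
extracting vein structure, and — the centerpiece of this package — a
**four-corners-in-one** warp that concentrates a sparse segmented leaf into a
dense square patch before a convolutional network sees it.  Because the
in-field image collections this machinery was designed around are not
publicly deposited, the package ships a first-class synthetic-leaf generator
that emulates them (six classes with distinct lobe counts and vein
orientations on cluttered backgrounds), so every capability is exercised and
tested end to end without any download.

## What it implements

* **`synthetic_leaf`** — reproducible leaf images with ground-truth masks and
  labels; generation is a pure function of `(params, dims, seed)`.
* **`segmentation`** — exact-black-background contract: a green-dominance
  stand-in segmenter, mask injection (`apply_mask`), and leaf-patch harvest
  (non-overlapping 64×64 tiles with zero background pixels).
* **`corners_warp`** — the four-corners-in-one method: per-row/per-column
  compaction of non-black pixels toward each corner, 180° rotation into a
  2×2 mosaic around a one-pixel white cross, extraction of the largest
  centered all-foreground square.  Purely pixel-rearranging.
* **`vein_extract`** — gray-scale morphology `g = (f·b − f) − (f − f∘b)`
  (bot-hat minus top-hat, square element of width 7) highlighting thin dark
  veins, and a Canny pipeline (σ = 1.75) with single-pixel speckle removal.
* **`icf_bank`** — independent-component filters: non-overlapping patches
  vectorized into a matrix (636×960 at p = 12 gives 144×4240), fixed-point
  FastICA, deterministic 25-filter selection (first three, last three, evenly
  spaced interior), channel-wise convolution, block grids.
* **`augment`** — sliding-crop translation with exact factor arithmetic
  (resize to `S = 227 + √F − 1`, enumerate all `F` one-pixel-shifted 227×227
  windows; `(S, F)` ∈ {(256, 900), (236, 100), (231, 25), (228, 4),
  (237, 121)}), horizontal mirror, and ±5° rotations.
* **`dataset_builder`** — ten declarative recipes binding pre-processing to
  augmentation, leakage-free raw-level splits (e.g. 224 images → 128/36/60),
  closed-form count audits, and manifest-producing builds.
* **`tl_harness`** — a backbone constructed from a declarative layer table
  (the classic 25-row, five-convolution architecture is dimension-verified:
  conv1 → 55×55×96, pool5 → 6×6×256, fc6 input 9216), a compact numpy CNN
  with exact backpropagation, SGD with momentum, early stopping on validation
  loss, per-epoch checkpoints, three transfer schemes (retrain all / freeze
  first two convs / frozen features + linear SVM), and confusion-matrix
  evaluation with optional per-raw-image majority voting.

## Worked example

`examples/` holds one short script per capability.  Running
`python examples/06_transfer_learning.py` prints:

```
reference backbone verified: 25 rows, conv1 -> (55, 55, 96), pool5 -> (6, 6, 256) (fc6 input 9216)
LAST3_CONV: 30 epochs, test accuracy 100.0% (chance 16.7%)
FE_SVM on fc6 features: CV accuracy 100.0% at C = 0.01
```

The first line confirms the reference architecture's printed dimensions
follow from the convolution arithmetic.  The second trains a reduced backbone
(same layer kinds, 32×32 inputs) on four-corners-warped synthetic leaves with
the first two convolutional layers frozen — 100% on a held-out test set where
chance is one in six.  The third freezes the whole backbone and feeds fc6
activations to a linear SVM with cross-validated grid search over C.

`python examples/05_dataset_recipes.py` prints the recipe count table — for
instance 140 raw images under recipe #1 (resize 256, F900) expand to 126,000
crops, and 164 raw images under recipe #9 (four-corners warp, F900 + mirror,
originals retained) to 295,364 — and materializes a scaled recipe end to end,
verifying the builder against the closed-form audit.

Command-line equivalents are available via `vineprep synth | segment |
corners | veins | audit | build`.

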
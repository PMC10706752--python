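# Methods

## Problem and model

The package classifies whole-slide histopathology images of odontogenic
keratocysts (OKC) as recurring or non-recurring. The decision is made at two
levels: a tile-level classifier assigns each informative 2048×2048 tile
(resized to 64×64 RGB) to one of the two classes, and a slide-level rule
thresholds the fraction of recurring tiles.

The tile classifier (ABISA — attention-based image sequence analyzer) is a
hybrid patch-transformer/LSTM:

* **Patch extraction.** The 64×64×3 input, scaled to [0, 1], is cut into
  non-overlapping 6×6 patches over the ⌊64/6⌋ = 10 per-axis grid in
  row-major order; the 4-pixel right/bottom strips outside the covered
  60×60 region are ignored. Each patch is flattened to a 108-vector.
* **Patch encoding.** A shared linear projection to d = 64 plus a learned
  positional embedding per patch index (a 100×64 table).
* **Transformer trunk.** Four identical blocks: multi-head self-attention
  (4 heads, per-head query/key/value width 64, scores scaled by 1/√64,
  dropout 0.1 on the attention probabilities), an element-wise skip
  connection with the block input, then layer normalization. A per-block
  position-wise feed-forward sub-layer is available behind
  `ModelConfig.use_block_ffn` (GELU, units [2d, d], its own skip + layer
  norm) but is **off by default**: the default layout is the one whose
  parameter totals match the reference architecture this package
  re-implements (see "Block layout" below).
* **LSTM.** A standard LSTM with 32 hidden/cell units runs over the
  100-token sequence in patch order and returns the full output sequence
  (100×32), compressing each token from width 64 to 32. Gate order
  (input, forget, cell, output); zero initial states; unit forget-gate
  bias; Glorot kernels and orthogonal recurrent kernels.
* **Head.** Layer norm → flatten (3200) → dropout 0.5 → Dense 2048 (GELU)
  → dropout 0.5 → Dense 1024 (GELU) → dropout 0.5 → Dense 2. Softmax is
  applied at prediction time; the training loss consumes logits.

The standard-ViT baseline is the identical network without the LSTM (the
64-wide tokens are flattened directly, 6400 → head). Since the first head
layer dominates the parameter count (flattened width × 2048), the LSTM
bottleneck makes ABISA strictly smaller whenever `lstm_units <
projection_dim`: 8,947,714 vs. 15,488,962 trainable parameters at the
defaults (a 42% reduction).

### Block layout

The block structure of the reference architecture is fixed by its model
summary rather than by prose, and two readings are defensible: with or
without a per-block FFN. Both are implemented. The package's default (no
per-block FFN; attention + skip + layer norm only) reproduces the reference
totals to within 7 parameters out of ~9M/15.5M — the residual is identical
for both architectures, so it sits in the shared trunk and does not affect
any architectural conclusion; the FFN variant is ~67k parameters away. The
totals reported by `scripts/acceptance.py` are computed by building the
models and summing tensor sizes, never assigned.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) with decoupled weight decay applied
to all parameters (plain L2 available via
`TrainConfig.decoupled_weight_decay = False`); learning rate 1e-4, weight
decay 1e-3, batch size 20, sparse categorical cross-entropy, default 25
epochs with best-validation-loss weight restoration. All randomness —
initialization, shuffling, dropout masks, augmentation — derives from the
config seeds, and repeated runs are bit-identical on one machine. The
network and its reverse-mode autodiff engine are pure numpy (float32);
gradients are validated against central finite differences in the test
suite (directional-derivative checks at tolerances consistent with float32
arithmetic).

## Tiling and the white-tile filter

Tiles are non-overlapping `tile_size` squares from the highest-resolution
slide level; partial edge tiles are discarded (floor grid), because the
classifier needs fixed-size inputs and the reference tile counts are
consistent with flooring. Grayscale is ITU-R BT.601 luma rounded to integer
bins. A tile is kept iff its histogram entropy ≥ 4.0 bits **and** its
grayscale variance ≥ 100 (failing either statistic marks it
low-information); the thresholds were left unspecified upstream, and these
defaults cleanly separate glass from tissue-like texture while remaining
configurable per run and logged in the manifest. Manifest ordering is
row-major, 0-based. Pyramidal TIFFs are read through tifffile (largest
level of the largest series); plain PNG/TIFF rasters are accepted as
single-level slides so tests need no pyramidal fixtures.

## Dataset pipeline

70-10-20 train/validation/test split: |test| = round(0.20 N) and |val| =
round(0.10 N) (half-up), training takes the remainder — 508 tiles therefore
yield a 102-tile test partition. Stratification allocates per-class counts
by largest remainder (deterministic tie-break: larger fractional part, then
larger class), guaranteeing per-class proportions within ±1 item for any
class sizes; splitting is by tile, not by slide (grouping by slide would
avoid cross-split leakage from one slide but is not the default behaviour
being reproduced). Resizing is bilinear (Pillow). Augmentation — rotation
±20°, width/height shift ±0.1 of size, shear ±0.2 (skimage shear
coefficient), zoom in [0.8, 1.2], fair-coin horizontal flip — is sampled
per image per batch (on the fly, not a pre-enlarged dataset), uses
nearest-edge fill for out-of-bounds pixels, and is applied to training
batches only.

## Metrics

All count-derived metrics are explicit closed forms from the 2×2 matrix
(class 1 = recurring = positive); scikit-learn serves as an independent
oracle in the tests, never as the implementation. Zero denominators yield
0.0 (rates, and MCC when a marginal vanishes). Score-dependent metrics
(Brier, log loss with probability clipping at 1e-15, trapezoidal ROC/AUC
over distinct-score thresholds) require per-sample probabilities and are
reported as absent — never silently zero — without them.
`reconstruct_confusion_from_report` inverts a printed binary classification
report (supports + recalls) back to integer counts and raises an ambiguity
error when recall × support is not integral within 1e-6. Values are kept at
full precision; `MetricsReport.rounded()` provides the 2-dp display form.
One known display quirk: on the matrix [[48, 2], [0, 52]] the G-mean is
√(1.0 × 0.96) = 0.9798, which rounds to 0.98.

## Slide aggregation

A slide is recurring iff n_recurring / n_classified ≥ threshold (default
0.15, inclusive — the boundary case was unspecified, and inclusiveness
makes the rule's decision regions closed). The denominator is all
classified (informative) tiles. Smaller slides may warrant a lower
threshold; this is a per-run override, not an automatic rule, since no
size-to-threshold mapping is defined. A slide with no informative tiles is
an explicit undecidable error rather than a default call.

## Synthetic data generator

The generator defines the study conditions for every test:

* **white** — constant level 245 with sparse ±1 sensor noise (5% of
  pixels): entropy ≈ 0.3 bits, variance ≈ 0.05, far below both filter
  thresholds.
* **non_recurring** — smoothed Gaussian noise (coarse σ = size/24 plus
  fine σ = size/128 components) modulating an eosin-pink palette
  (226, 171, 204) with per-channel depths (22, 46, 26): grayscale entropy
  ≈ 6 bits, variance ≈ 250–300, comfortably above the thresholds.
* **recurring** — the same texture plus one smooth horizontal
  high-saturation band (color (148, 38, 128), cosine-rolled edges), height
  20–40% of the tile, centre between 40% and 60% of the height so it
  always overlaps the central rows.

The band emulates a single discriminative feature — the subepithelial
hyalinization band — because the tests need a learnable, verifiable signal,
not biological realism; real OKC recurrence correlates with several further
features (corrugated surface, incomplete lining, satellite cysts) that are
not modelled, and the generator has none of the stain variability, blur,
pen marks or tissue-fold artifacts of scanned slides. Passing tests
therefore demonstrate the pipeline's mechanics and the architecture's
capacity to learn a spatial texture/band distinction, not clinical
performance. Class separability is enforced as a tested invariant: the
trivial rule "mean centre-band saturation thresholded at the midpoint of
the class means" reaches ≥ 0.90 accuracy on a 100-tile set, so a trained
model failing would indicate a defect, not an impossible task.

Composite slides place exactly round(fraction × cells) recurring and white
tiles at seeded positions, with a ground-truth manifest per cell.

## Problem sizes used in the checks

The end-to-end training check uses 400 synthetic tiles (200 per class) at
64×64, split 280/40/80, trained 10 epochs at batch 20 and lr 1e-4 — about a
minute of CPU time — and must reach ≥ 0.90 held-out accuracy; slide-level
recovery uses 10×10-tile grids (tile size 64, 10% white) at recurring
fractions 0.30 and 0.02, chosen so the slide call is robust to several
percent of tile-level error. These sizes keep the full suite fast while
leaving wide margins to the thresholds.

## Known limitations

* No SVS/OpenSlide reader: pyramidal TIFF via tifffile and plain rasters
  only.
* Binary classes only; the metric battery is deliberately 2×2.
* No stain normalization, blur/artifact detection, or spatial smoothing of
  tile predictions.
* CPU-scale training only; the numpy engine is single-device and eager.
* The 7-parameter residual between the default layout's totals and the
  reference totals is unexplained (the reference summary is not available
  at tensor granularity); it is documented rather than absorbed.
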
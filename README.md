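# abisa

Automated risk stratification of odontogenic keratocysts (OKC) from
whole-slide histopathology images. OKC is a benign but aggressive jaw cyst
with a high post-surgical recurrence rate; whether a lesion will recur is
hard to call from clinical and radiographic features alone, and the
histological correlates (notably a band of subepithelial hyalinization) are
tedious to assess across a multi-gigapixel slide. This package implements a
tile-based pipeline that automates the call, for computational-pathology
researchers and for engineers who want a fully reproducible, dependency-light
reference implementation:

1. **Tiling** — the slide's highest-resolution level is cut into
   non-overlapping 2048×2048 tiles; background/glass ("white") tiles are
   rejected when the Shannon entropy *H* = −Σᵢ pᵢ log₂ pᵢ of the 256-bin
   grayscale histogram or the grayscale variance falls below a threshold
   (defaults: 4 bits, 100).
2. **Tile classification** — each kept tile, resized to 64×64 RGB, is
   classified recurring vs. non-recurring by the **attention-based image
   sequence analyzer (ABISA)**: the image is cut into ⌊64/6⌋² = 100
   patches of 6×6 px, each patch is linearly embedded to d = 64 with a
   learned positional term, four multi-head self-attention blocks
   (4 heads, per-head key dim 64; Attention(Q,K,V) = softmax(QKᵀ/√dₖ)V,
   skip connection, layer norm) refine the token sequence, an LSTM with 32
   units runs over the patch order and returns the full output sequence, and
   a GELU MLP head [2048, 1024] maps the flattened sequence to two softmax
   classes. Replacing the 64-wide tokens with 32-wide LSTM outputs before
   the wide head is what makes ABISA markedly smaller than the standard
   vision transformer built from the same hyperparameters (8,947,714 vs.
   15,488,962 trainable parameters).
3. **Slide aggregation** — a slide is called *recurring* when the fraction
   of its classified tiles predicted recurring meets or exceeds a threshold
   (15% by default, inclusive).

The network, including a small reverse-mode autodiff engine, is implemented
in pure numpy — there is no deep-learning framework dependency — and
training (Adam with decoupled weight decay, sparse categorical
cross-entropy, batch 20, lr 1e-4) is fully seeded and bit-reproducible.

Because clinical slide archives are private, the package ships a
deterministic synthetic-data generator: two-class histology-like tiles
(speckled eosin-pink texture, with or without a smooth high-saturation
horizontal band emulating subepithelial hyalinization), white tiles for the
filter, and composite grid slides with exact ground-truth class counts.
Every stage of the pipeline is tested end to end against it.

## Worked example

```python
from abisa import (reconstruct_confusion_from_report, compute_metrics,
                   decide_slide)
from abisa.model import (ModelConfig, build_abisa, build_standard_vit,
                         count_trainable_parameters)

# a published-style classification report (supports 50/52, recalls 0.96/1.00)
cm = reconstruct_confusion_from_report(50, 0.96, 52, 1.00)
print(cm.as_array().tolist())      # [[48, 2], [0, 52]]
rep = compute_metrics(cm).rounded()
print(rep["accuracy"], rep["mcc"], rep["sensitivity"], rep["youden_j"])
# 0.98 0.96 1.0 0.96

# slide-level call: 751 recurring tiles of 3844 classified
d = decide_slide(751, 3844)
print(d.predicted_label, round(d.recurring_fraction, 4))
# recurring 0.1954   (>= the 0.15 threshold)

cfg = ModelConfig()
print(count_trainable_parameters(build_abisa(cfg)))         # 8947714
print(count_trainable_parameters(build_standard_vit(cfg)))  # 15488962
```

The confusion matrix is recovered exactly from the per-class supports and
recalls (in a binary problem every error of one class lands in the other);
the metric battery on it gives accuracy 0.98, Matthews correlation 0.96,
sensitivity 1.0 and Youden's J 0.96 at two-decimal display rounding. The
slide decision shows the inclusive 15% threshold rule, and the two
parameter counts quantify the LSTM bottleneck's saving (ABISA is ~42%
smaller than the ViT baseline).

Training on synthetic data end to end:

```sh
abisa train --n-per-class 200 --epochs 10 --out ckpt --seed 1
# test accuracy 1.000; checkpoint in ckpt
abisa summary            # layer tables + totals for both architectures
```

## Command-line interface

`abisa tile` (tile + filter a slide), `abisa synth` (generate synthetic
tiles), `abisa train`, `abisa summary`, `abisa evaluate` (metric battery
from a predictions CSV), `abisa predict-slide` (full pipeline on one slide).
Run any of them with `--help` for options.

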
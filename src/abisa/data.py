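"""Dataset splitting, tile resizing, and training-time augmentation.

The split follows a 70-10-20 train/validation/test rule with test and
validation sizes rounded to the nearest integer and the remainder going to
training (508 labeled tiles therefore give a 102-tile test partition).
Stratified splitting keeps per-class proportions within one item using a
largest-remainder allocation, so the contract holds even for tiny classes.

Augmentation mirrors the common image-data-generator recipe: per-image
random affine transforms (rotation, width/height shift, shear, zoom) plus a
fair-coin horizontal flip, applied to training batches only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, warp


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.70
    val_frac: float = 0.10
    test_frac: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1.0")
        if min(self.train_frac, self.val_frac, self.test_frac) < 0:
            raise ValueError("split fractions must be non-negative")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_range_deg: float = 20.0
    width_shift_frac: float = 0.1
    height_shift_frac: float = 0.1
    shear_range: float = 0.2
    zoom_range: float = 0.2
    horizontal_flip: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_range_deg", "width_shift_frac",
                     "height_shift_frac", "shear_range", "zoom_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.rotation_range_deg == 0 and self.width_shift_frac == 0
                and self.height_shift_frac == 0 and self.shear_range == 0
                and self.zoom_range == 0 and not self.horizontal_flip)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _allocate(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` across groups ~ counts."""
    n = counts.sum()
    quota = counts * total / n
    base = np.floor(quota).astype(int)
    remainder = total - base.sum()
    if remainder > 0:
        frac = quota - base
        # deterministic tie-break: larger fractional part, then larger class
        order = np.lexsort((-counts, -frac))
        base[order[:remainder]] += 1
    return base


def split_dataset(labels, cfg: SplitConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition item indices into (train, val, test) index arrays.

    ``labels`` is a length-N sequence of class labels (any hashable values);
    with ``stratified=False`` only its length is used. |test| and |val| are
    the fractions rounded to nearest; training takes the remainder. The
    three sets are disjoint, exhaustive, and deterministic in the seed.
    """
    cfg = cfg or SplitConfig()
    labels = np.asarray(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    n_test = _round_half_up(cfg.test_frac * n)
    n_val = _round_half_up(cfg.val_frac * n)
    rng = np.random.default_rng(cfg.seed)

    if not cfg.stratified:
        order = rng.permutation(n)
        test = order[:n_test]
        val = order[n_test:n_test + n_val]
        train = order[n_test + n_val:]
        return np.sort(train), np.sort(val), np.sort(test)

    classes, class_idx = np.unique(labels, return_inverse=True)
    counts = np.bincount(class_idx)
    if (counts == 0).any():
        raise ValueError("every class must be non-empty for a stratified split")
    test_alloc = _allocate(counts, n_test)
    val_alloc = _allocate(counts - test_alloc, n_val)

    train_parts, val_parts, test_parts = [], [], []
    for c in range(len(classes)):
        idx = np.flatnonzero(class_idx == c)
        idx = idx[rng.permutation(len(idx))]
        t, v = test_alloc[c], val_alloc[c]
        test_parts.append(idx[:t])
        val_parts.append(idx[t:t + v])
        train_parts.append(idx[t + v:])
    return (np.sort(np.concatenate(train_parts)),
            np.sort(np.concatenate(val_parts)),
            np.sort(np.concatenate(test_parts)))


def resize_tile(pixels: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize to target x target x 3, values clipped to [0, 255]."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty input tile")
    if target < 1:
        raise ValueError("target size must be >= 1")
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    arr = np.clip(pixels, 0, 255).astype(np.uint8)
    if arr.shape[0] == target and arr.shape[1] == target:
        return arr.copy()
    out = Image.fromarray(arr).resize((target, target), Image.BILINEAR)
    return np.asarray(out)


def _sample_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    return {
        "rotation": rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg),
        "tx": rng.uniform(-cfg.width_shift_frac, cfg.width_shift_frac),
        "ty": rng.uniform(-cfg.height_shift_frac, cfg.height_shift_frac),
        "shear": rng.uniform(-cfg.shear_range, cfg.shear_range),
        "zoom": rng.uniform(1.0 - cfg.zoom_range, 1.0 + cfg.zoom_range),
        "flip": cfg.horizontal_flip and rng.random() < 0.5,
    }


def _apply_affine(image: np.ndarray, p: dict) -> np.ndarray:
    h, w = image.shape[:2]
    center = np.array([w, h]) / 2.0 - 0.5
    # rotate/shear/zoom about the image centre, then shift
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=np.deg2rad(p["rotation"]),
                               shear=p["shear"],
                               scale=(p["zoom"], p["zoom"]))
             + AffineTransform(translation=center
                               + np.array([p["tx"] * w, p["ty"] * h])))
    out = warp(image.astype(np.float64), tform.inverse, order=1,
               mode="edge", preserve_range=True)
    if p["flip"]:
        out = out[:, ::-1]
    return out


def augment_batch(images: np.ndarray, cfg: AugmentConfig | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Independently transform each image in the batch; shape preserved.

    With every range zero and flipping off, the output equals the input.
    Deterministic in ``cfg.seed`` when no generator is supplied.
    """
    cfg = cfg or AugmentConfig()
    images = np.asarray(images)
    single = images.ndim == 3
    if single:
        images = images[None]
    if cfg.is_identity:
        return images[0].copy() if single else images.copy()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    was_int = np.issubdtype(images.dtype, np.integer)
    out = np.empty(images.shape, dtype=np.float64)
    for i, im in enumerate(images):
        out[i] = _apply_affine(im.astype(np.float64), _sample_params(cfg, rng))
    out = np.clip(out, 0, 255)
    if was_int:
        out = np.rint(out).astype(images.dtype)
    else:
        out = out.astype(images.dtype)
    return out[0] if single else out


def make_augmenter(cfg: AugmentConfig):
    """Adapt an AugmentConfig into the ``(batch, rng) -> batch`` callable the
    training loop applies to training batches only."""
    def fn(batch, rng):
        return augment_batch(batch, cfg, rng=rng)
    return fn
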
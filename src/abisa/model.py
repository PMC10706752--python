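"""The attention-based image sequence analyzer (ABISA) and its ViT baseline.

ABISA is a hybrid tile classifier for histopathology: a 64x64 RGB tile is
cut into non-overlapping 6x6 patches, each patch is linearly embedded with a
learned positional term, a stack of multi-head self-attention blocks
(attention -> skip connection -> layer normalization) refines the patch
sequence, an LSTM then runs over the patch order and compresses each token
from ``projection_dim`` to ``lstm_units`` while modelling sequential
dependencies, and a GELU MLP head maps the flattened sequence to two class
logits (0 = non-recurring, 1 = recurring). The standard-ViT baseline is the
same network without the LSTM; because the LSTM narrows every token before
the wide MLP head, ABISA has strictly fewer trainable parameters whenever
``lstm_units < projection_dim``.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (
    Dense,
    LSTM,
    Layer,
    LayerNorm,
    MultiHeadSelfAttention,
    PositionalPatchEncoder,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "extract_patches",
    "build_abisa",
    "build_standard_vit",
    "count_trainable_parameters",
    "train",
    "predict_tiles",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters shared by ABISA and the ViT baseline."""

    image_size: int = 64
    patch_size: int = 6
    projection_dim: int = 64
    num_heads: int = 4
    key_dim: int = 64          # per-head query/key/value width
    transformer_layers: int = 4
    attention_dropout: float = 0.1
    lstm_units: int = 32
    head_dropout: float = 0.5
    mlp_head_units: tuple[int, ...] = (2048, 1024)
    num_classes: int = 2
    # The published layout uses attention + skip + layer-norm blocks with no
    # per-block feed-forward sub-layer; flip this on for the textbook
    # transformer block with a GELU FFN and a second skip + layer-norm.
    use_block_ffn: bool = False
    block_ffn_units: tuple[int, ...] | None = None

    @property
    def num_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * 3

    def ffn_units(self) -> tuple[int, ...]:
        if self.block_ffn_units is not None:
            return tuple(self.block_ffn_units)
        return (2 * self.projection_dim, self.projection_dim)

    def validate(self) -> None:
        if self.patch_size < 1 or self.patch_size > self.image_size:
            raise ValueError("patch_size must be in [1, image_size]")
        for name in ("projection_dim", "num_heads", "key_dim",
                     "transformer_layers", "lstm_units", "num_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("attention_dropout", "head_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    decoupled_weight_decay: bool = True   # AdamW-style; False -> plain L2
    batch_size: int = 20
    epochs: int = 25
    early_stop_on_val: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def extract_patches(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut an H x W x 3 image into flattened non-overlapping square patches.

    Patches are taken in row-major order over the floor(H/p) x floor(W/p)
    grid; pixels beyond the covered region are ignored (for a 64-pixel image
    and 6-pixel patches, the right/bottom 4-pixel strips). Returns an array
    of shape (n_patches, patch_size*patch_size*channels).
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected an H x W x C image array")
    h, w, ch = image.shape
    p = patch_size
    if p < 1 or p > h or p > w:
        raise ValueError("patch_size must be in [1, min(H, W)]")
    gh, gw = h // p, w // p
    cropped = image[: gh * p, : gw * p]
    blocks = cropped.reshape(gh, p, gw, p, ch).transpose(0, 2, 1, 3, 4)
    return blocks.reshape(gh * gw, p * p * ch)


def assemble_patches(patches: np.ndarray, image_size: int, patch_size: int,
                     channels: int = 3) -> np.ndarray:
    """Inverse of :func:`extract_patches` for fully covered images."""
    p = patch_size
    g = image_size // p
    blocks = patches.reshape(g, g, p, p, channels).transpose(0, 2, 1, 3, 4)
    return blocks.reshape(g * p, g * p, channels)


class _TransformerBlock(Layer):
    def __init__(self, rng, cfg: ModelConfig, index: int):
        d = cfg.projection_dim
        self.attention = MultiHeadSelfAttention(
            rng, d, cfg.num_heads, cfg.key_dim,
            dropout_rate=cfg.attention_dropout, name=f"block{index}/mhsa")
        self.norm = LayerNorm(d, name=f"block{index}/norm")
        self.ffn: list[Dense] | None = None
        self.ffn_norm: LayerNorm | None = None
        self.ffn_dropout = cfg.attention_dropout
        if cfg.use_block_ffn:
            units = cfg.ffn_units()
            dims = [d, *units]
            self.ffn = [
                Dense(rng, dims[i], dims[i + 1], activation="gelu",
                      name=f"block{index}/ffn{i}")
                for i in range(len(units))
            ]
            self.ffn_norm = LayerNorm(units[-1], name=f"block{index}/ffn_norm")

    def parameters(self):
        params = self.attention.parameters() + self.norm.parameters()
        if self.ffn is not None:
            for d in self.ffn:
                params += d.parameters()
            params += self.ffn_norm.parameters()
        return params

    def __call__(self, x, *, training=False, rng=None):
        attn = self.attention(x, training=training, rng=rng)
        x = self.norm(attn + x)
        if self.ffn is not None:
            y = x
            for dense in self.ffn:
                y = dense(y)
                y = ag.dropout(y, self.ffn_dropout, rng, training)
            x = self.ffn_norm(y + x)
        return x


class SequenceClassifier:
    """Shared forward machinery for ABISA and the ViT baseline."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, with_lstm: bool = True):
        cfg.validate()
        if cfg.use_block_ffn and cfg.ffn_units()[-1] != cfg.projection_dim:
            raise ValueError("block FFN must return to projection_dim for the skip path")
        self.config = cfg
        self.with_lstm = with_lstm
        rng = np.random.default_rng(seed)
        self.encoder = PositionalPatchEncoder(
            rng, cfg.num_patches, cfg.patch_dim, cfg.projection_dim)
        self.blocks = [_TransformerBlock(rng, cfg, i)
                       for i in range(cfg.transformer_layers)]
        token_width = cfg.projection_dim
        self.lstm: LSTM | None = None
        if with_lstm:
            self.lstm = LSTM(rng, cfg.projection_dim, cfg.lstm_units)
            token_width = cfg.lstm_units
        self.final_norm = LayerNorm(token_width, name="final_norm")
        dims = [cfg.num_patches * token_width, *cfg.mlp_head_units]
        self.head = [
            Dense(rng, dims[i], dims[i + 1], activation="gelu", name=f"head{i}")
            for i in range(len(cfg.mlp_head_units))
        ]
        self.classifier = Dense(rng, dims[-1], cfg.num_classes, name="classifier")

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = self.encoder.parameters()
        for b in self.blocks:
            params += b.parameters()
        if self.lstm is not None:
            params += self.lstm.parameters()
        params += self.final_norm.parameters()
        for d in self.head:
            params += d.parameters()
        params += self.classifier.parameters()
        return params

    def summary(self) -> list[tuple[str, tuple[int, ...], int]]:
        return [(p.name or "param", p.shape, p.size) for p in self.parameters()]

    # -- forward -----------------------------------------------------------
    def _patchify(self, images: np.ndarray) -> np.ndarray:
        cfg = self.config
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1:3] != (cfg.image_size, cfg.image_size) or images.shape[3] != 3:
            raise ValueError(
                f"expected (N, {cfg.image_size}, {cfg.image_size}, 3) images, "
                f"got {images.shape}")
        if images.max() > 1.5:  # accept 8-bit input, scale to [0, 1]
            images = images / np.float32(255.0)
        return np.stack([extract_patches(im, cfg.patch_size) for im in images])

    def forward(self, images: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Return class logits of shape (N, num_classes)."""
        cfg = self.config
        x = self.encoder(Tensor(self._patchify(images)))
        for block in self.blocks:
            x = block(x, training=training, rng=rng)
        if self.lstm is not None:
            x = self.lstm(x)
        x = self.final_norm(x)
        n = x.shape[0]
        x = ag.reshape(x, (n, x.shape[1] * x.shape[2]))
        x = ag.dropout(x, cfg.head_dropout, rng, training)
        for dense in self.head:
            x = dense(x)
            x = ag.dropout(x, cfg.head_dropout, rng, training)
        return self.classifier(x)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        out = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(images[start:start + batch_size], training=False)
            out.append(ag.softmax(logits, axis=-1).data)
        return np.concatenate(out, axis=0)

    # -- state -------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match parameter list")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = np.asarray(w, dtype=np.float32)


def build_abisa(cfg: ModelConfig | None = None, seed: int = 0) -> SequenceClassifier:
    """Patch encoder -> attention stack -> LSTM -> norm/flatten -> MLP head."""
    return SequenceClassifier(cfg or ModelConfig(), seed=seed, with_lstm=True)


def build_standard_vit(cfg: ModelConfig | None = None, seed: int = 0) -> SequenceClassifier:
    """Identical trunk without the LSTM: the flattened tokens feed the head."""
    return SequenceClassifier(cfg or ModelConfig(), seed=seed, with_lstm=False)


def count_trainable_parameters(model: SequenceClassifier) -> int:
    return int(sum(p.size for p in model.parameters()))


# -- loss and training --------------------------------------------------------

def sparse_categorical_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-probability of the integer true class."""
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be one integer per example")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k - 1}]")
    logp = ag.log_softmax(logits, axis=-1)
    picked = logp[np.arange(n), labels]
    return -ag.reduce_mean(picked)


class AdamOptimizer:
    """Adam with decoupled (AdamW-style) or L2-coupled weight decay."""

    def __init__(self, params: list[Tensor], learning_rate: float = 1e-4,
                 weight_decay: float = 0.0, decoupled: bool = True,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = learning_rate
        self.wd = weight_decay
        self.decoupled = decoupled
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.wd and not self.decoupled:
                g = g + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.wd and self.decoupled:
                update = update + self.wd * p.data
            p.data = p.data - np.float32(self.lr) * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _evaluate(model: SequenceClassifier, images, labels, batch_size: int):
    probs = model.predict_proba(images, batch_size=batch_size)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == np.asarray(labels)))
    return loss, acc


def train(model: SequenceClassifier,
          train_images: np.ndarray, train_labels: np.ndarray,
          cfg: TrainConfig,
          val_images: np.ndarray | None = None,
          val_labels: np.ndarray | None = None,
          augment=None) -> dict:
    """Fit the classifier; returns a per-epoch history dict.

    ``augment``, when given, is a callable ``(images, rng) -> images`` applied
    to each training batch only. With ``early_stop_on_val`` the weights of
    the best validation-loss epoch are restored at the end. All randomness
    (shuffling, dropout, augmentation) derives from ``cfg.seed``.
    """
    cfg.validate()
    train_labels = np.asarray(train_labels)
    if train_labels.min() < 0 or train_labels.max() >= model.config.num_classes:
        raise ValueError("labels out of range for the configured class count")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamOptimizer(model.parameters(), learning_rate=cfg.learning_rate,
                        weight_decay=cfg.weight_decay,
                        decoupled=cfg.decoupled_weight_decay)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val = np.inf
    best_weights = None
    n = len(train_images)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = np.asarray(train_images[idx], dtype=np.float32)
            if augment is not None:
                batch = augment(batch, rng)
            logits = model.forward(batch, training=True, rng=rng)
            loss = sparse_categorical_cross_entropy(logits, train_labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int((logits.data.argmax(axis=1) == train_labels[idx]).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        if val_images is not None and len(val_images):
            vl, va = _evaluate(model, val_images, val_labels, cfg.batch_size)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            if cfg.early_stop_on_val and vl < best_val:
                best_val = vl
                best_weights = model.get_weights()
    if best_weights is not None:
        model.set_weights(best_weights)
    return history


def predict_tiles(model: SequenceClassifier, tiles: np.ndarray,
                  batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Batched inference: (probabilities (N, C), argmax labels (N,))."""
    probs = model.predict_proba(tiles, batch_size=batch_size)
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite probabilities from the model")
    return probs, probs.argmax(axis=1)


# -- persistence --------------------------------------------------------------

def save_model(model: SequenceClassifier, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["with_lstm"] = model.with_lstm
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))
    arrays = {f"w{i:04d}": w for i, w in enumerate(model.get_weights())}
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory) -> SequenceClassifier:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    with_lstm = cfg.pop("with_lstm")
    for key in ("mlp_head_units", "block_ffn_units"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    model = SequenceClassifier(ModelConfig(**cfg), with_lstm=with_lstm)
    with np.load(directory / "weights.npz") as data:
        model.set_weights([data[k] for k in sorted(data.files)])
    return model
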
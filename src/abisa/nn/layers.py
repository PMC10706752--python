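"""Neural-network layers built on the autograd engine.

Initialization conventions follow the common Keras defaults the architecture
mirrors: Glorot-uniform dense kernels, zero biases, uniform(-0.05, 0.05)
embeddings, orthogonal LSTM recurrent kernels with a unit forget-gate bias.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor, parameter


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return q[:rows, :cols].astype(np.float32)


class Layer:
    name: str = "layer"

    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor, *, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int, activation: str | None = None,
                 name: str = "dense"):
        self.kernel = parameter(glorot_uniform(rng, n_in, n_out), name=f"{name}/kernel")
        self.bias = parameter(np.zeros(n_out, dtype=np.float32), name=f"{name}/bias")
        self.activation = activation
        self.name = name

    def parameters(self):
        return [self.kernel, self.bias]

    def __call__(self, x, *, training=False, rng=None):
        y = x @ self.kernel + self.bias
        if self.activation == "gelu":
            y = ag.gelu(y)
        elif self.activation == "tanh":
            y = ag.tanh(y)
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y


class LayerNorm(Layer):
    """Layer normalization over the last axis, with learned gain and bias."""

    def __init__(self, width: int, eps: float = 1e-6, name: str = "layer_norm"):
        self.gamma = parameter(np.ones(width, dtype=np.float32), name=f"{name}/gamma")
        self.beta = parameter(np.zeros(width, dtype=np.float32), name=f"{name}/beta")
        self.eps = np.float32(eps)
        self.name = name

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x, *, training=False, rng=None):
        mu = ag.reduce_mean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = ag.reduce_mean(centered * centered, axis=-1, keepdims=True)
        inv = ag.power(var + Tensor(self.eps), -0.5)
        return centered * inv * self.gamma + self.beta


class PositionalPatchEncoder(Layer):
    """Linear projection of flattened patches plus a learned positional table.

    Output_i = W patch_i + b + E[i] for patch index i in row-major order.
    """

    def __init__(self, rng, num_patches: int, patch_dim: int, projection_dim: int,
                 name: str = "patch_encoder"):
        self.projection = Dense(rng, patch_dim, projection_dim, name=f"{name}/projection")
        self.position_embedding = parameter(
            rng.uniform(-0.05, 0.05, size=(num_patches, projection_dim)).astype(np.float32),
            name=f"{name}/position_embedding",
        )
        self.name = name

    def parameters(self):
        return self.projection.parameters() + [self.position_embedding]

    def __call__(self, x, *, training=False, rng=None):
        return self.projection(x) + self.position_embedding


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with ``num_heads`` parallel heads.

    Each head uses ``key_dim`` for queries, keys and values; the concatenated
    head outputs are projected back to ``model_dim``. Dropout is applied to
    the attention probabilities during training.
    """

    def __init__(self, rng, model_dim: int, num_heads: int, key_dim: int,
                 dropout_rate: float = 0.0, name: str = "mhsa"):
        total = num_heads * key_dim
        self.wq = Dense(rng, model_dim, total, name=f"{name}/query")
        self.wk = Dense(rng, model_dim, total, name=f"{name}/key")
        self.wv = Dense(rng, model_dim, total, name=f"{name}/value")
        self.wo = Dense(rng, total, model_dim, name=f"{name}/output")
        self.num_heads = num_heads
        self.key_dim = key_dim
        self.dropout_rate = dropout_rate
        self.name = name
        self._last_attention = None  # (B, H, P, P) probabilities, for inspection

    def parameters(self):
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())

    def _split_heads(self, t: Tensor, batch: int, seq: int) -> Tensor:
        t = ag.reshape(t, (batch, seq, self.num_heads, self.key_dim))
        return ag.transpose(t, (0, 2, 1, 3))

    def __call__(self, x, *, training=False, rng=None):
        batch, seq, _ = x.shape
        q = self._split_heads(self.wq(x), batch, seq)
        k = self._split_heads(self.wk(x), batch, seq)
        v = self._split_heads(self.wv(x), batch, seq)
        scale = Tensor(np.float32(1.0 / np.sqrt(self.key_dim)))
        scores = (q @ ag.transpose(k, (0, 1, 3, 2))) * scale
        probs = ag.softmax(scores, axis=-1)
        self._last_attention = probs.data
        probs = ag.dropout(probs, self.dropout_rate, rng, training)
        context = probs @ v  # (B, H, P, key_dim)
        context = ag.transpose(context, (0, 2, 1, 3))
        context = ag.reshape(context, (batch, seq, self.num_heads * self.key_dim))
        return self.wo(context)


class LSTM(Layer):
    """Standard LSTM returning the full output sequence.

    Gate order follows the (input, forget, cell, output) convention; hidden
    and cell states start at zero and the forget-gate bias at one.
    Trainable size is 4*((n_in + units)*units + units).
    """

    def __init__(self, rng, n_in: int, units: int, name: str = "lstm"):
        self.kernel = parameter(
            glorot_uniform(rng, n_in, 4 * units, shape=(n_in, 4 * units)),
            name=f"{name}/kernel")
        rec = np.concatenate(
            [orthogonal(rng, units, units) for _ in range(4)], axis=1)
        self.recurrent_kernel = parameter(rec, name=f"{name}/recurrent_kernel")
        bias = np.zeros(4 * units, dtype=np.float32)
        bias[units:2 * units] = 1.0  # unit forget-gate bias
        self.bias = parameter(bias, name=f"{name}/bias")
        self.units = units
        self.name = name

    def parameters(self):
        return [self.kernel, self.recurrent_kernel, self.bias]

    def __call__(self, x, *, training=False, rng=None):
        batch, seq, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((batch, u), dtype=np.float32))
        c = Tensor(np.zeros((batch, u), dtype=np.float32))
        outputs = []
        for t in range(seq):
            x_t = x[:, t, :]
            z = x_t @ self.kernel + h @ self.recurrent_kernel + self.bias
            i = ag.sigmoid(z[:, 0 * u:1 * u])
            f = ag.sigmoid(z[:, 1 * u:2 * u])
            g = ag.tanh(z[:, 2 * u:3 * u])
            o = ag.sigmoid(z[:, 3 * u:4 * u])
            c = f * c + i * g
            h = o * ag.tanh(c)
            outputs.append(h)
        return ag.stack(outputs, axis=1)  # (B, seq, units)
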
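"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the patch-transformer/LSTM classifier needs:
broadcasting arithmetic, (batched) matmul, reshape/transpose/slicing/stack,
reductions, the usual activations, and numerically stable (log-)softmax.
All tensors are float32. Gradients are accumulated by a single backward pass
over a topologically ordered tape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (produced under broadcasting) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        arr = np.asarray(data, dtype=np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = backward
        self._parents = tuple(parents)
        self.name = name

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction helpers ---------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=False)
        else:
            self.grad = self.grad + grad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    # -- backward pass ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, name: str | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def _make(data, parents, backward):
    if any(p.requires_grad or p._backward is not None for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- elementwise -------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accum(_sum_to_shape(g, a.data.shape))
        b._accum(_sum_to_shape(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(-g)

    return _make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accum(_sum_to_shape(g * b.data, a.data.shape))
        b._accum(_sum_to_shape(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        a._accum(_sum_to_shape(g / b.data, a.data.shape))
        b._accum(_sum_to_shape(-g * out_data / b.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data ** exponent

    def backward(g):
        a._accum(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    """Gaussian Error Linear Unit, exact erf form: x * Phi(x)."""
    x = a.data
    phi_cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    out_data = (x * phi_cdf).astype(np.float32)

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        a._accum(g * (phi_cdf + x * pdf).astype(np.float32))

    return _make(out_data, (a,), backward)


# -- linear algebra -----------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accum(_sum_to_shape(ga, a.data.shape))
        b._accum(_sum_to_shape(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- shape manipulation -------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def getitem(a: Tensor, key) -> Tensor:
    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, key, g)
        a._accum(full)

    return _make(a.data[key], (a,), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            t._accum(np.squeeze(piece, axis=axis))

    return _make(out_data, tuple(tensors), backward)


# -- reductions ---------------------------------------------------------------

def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        denom = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        denom = int(np.prod([a.data.shape[ax] for ax in axes]))
    s = reduce_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, Tensor(np.float32(1.0 / denom)))


# -- softmax family -----------------------------------------------------------

def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    soft = np.exp(out_data)

    def backward(g):
        a._accum(g - soft * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return a
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(a.data.shape) >= rate).astype(np.float32) / np.float32(1.0 - rate)
    return mul(a, Tensor(mask))
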
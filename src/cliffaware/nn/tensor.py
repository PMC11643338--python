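"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's tensor engine: a :class:`Tensor` wraps a float64
``numpy`` array and records, for every operation, how to push a gradient
back to its inputs.  The op set is exactly what the graph encoders and the
loss family need — elementwise arithmetic, matmul, reductions, gathers and
segment (per-graph / per-node) reductions — nothing more.

Gradients are dense float64 arrays.  ``backward()`` runs a topological
sort of the recorded graph and accumulates gradients into every tensor
created with ``requires_grad=True`` (parameters) or derived from one.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather_rows",
    "index2d",
    "segment_sum",
    "segment_max",
    "segment_mean",
    "segment_min",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_links", "requires_grad")

    def __init__(self, data, links=(), requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        # keep only links to tensors that actually need gradients
        self._links = tuple((p, fn) for p, fn in links if p.requires_grad)
        self.requires_grad = requires_grad or bool(self._links)
        self.grad = None

    # -- graph traversal -------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._links:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._links:
                g = fn(node.grad)
                # accumulation below always allocates fresh arrays, so
                # aliasing g with node.grad is safe
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            links=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, links=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            links=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            links=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def back(g):
            # subgradient 0 where the derivative blows up (base 0, e < 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = e * self.data ** (e - 1.0)
            return g * np.where(np.isfinite(d), d, 0.0)

        return Tensor(self.data**e, links=((self, back),))

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            links=(
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ),
        )

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, links=((self, lambda g: g * mask),))

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)
        return Tensor(self.data * factor, links=((self, lambda g: g * factor),))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), links=((self, lambda g: g * sign),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, links=((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), links=((self, lambda g: g / self.data),))

    def sqrt(self):
        out = np.sqrt(self.data)

        def back(g):
            # subgradient 0 at exactly zero (hinge distances of coincident
            # latent points)
            with np.errstate(divide="ignore"):
                d = 0.5 / out
            return g * np.where(out > 0, d, 0.0)

        return Tensor(out, links=((self, back),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, links=((self, lambda g: g * out * (1.0 - out)),))

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), links=((self, back),))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(*shape), links=((self, lambda g: g.reshape(orig)),)
        )


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- structural ops ---------------------------------------------------------


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_back(i):
        lo, hi = offsets[i], offsets[i + 1]

        def back(g):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            return g[tuple(idx)]

        return back

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        links=tuple((t, make_back(i)) for i, t in enumerate(tensors)),
    )


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]``; gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.intp)

    def back(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(t.data[idx], links=((t, back),))


def index2d(t: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Elementwise pick ``t[rows, cols]`` from a matrix."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)

    def back(g):
        out = np.zeros_like(t.data)
        np.add.at(out, (rows, cols), g)
        return out

    return Tensor(t.data[rows, cols], links=((t, back),))


def segment_sum(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Row-wise sum of ``t`` grouped by ``segments`` (shape [n_segments, ...])."""
    segments = np.asarray(segments, dtype=np.intp)
    out = np.zeros((n_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, segments, t.data)
    return Tensor(out, links=((t, lambda g: g[segments]),))


def segment_mean(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    segments = np.asarray(segments, dtype=np.intp)
    counts = np.bincount(segments, minlength=n_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0).reshape((-1,) + (1,) * (t.data.ndim - 1))
    return segment_sum(t, segments, n_segments) / Tensor(counts)


def segment_max(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Row-wise max per segment.  Empty segments raise.

    Subgradient convention: at ties the gradient is routed to every
    attaining element (ties are measure-zero for learned features).
    """
    segments = np.asarray(segments, dtype=np.intp)
    counts = np.bincount(segments, minlength=n_segments)
    if (counts == 0).any():
        raise ValueError("segment_max: empty segment (graph with zero nodes?)")
    out = np.full((n_segments,) + t.data.shape[1:], -np.inf, dtype=np.float64)
    np.maximum.at(out, segments, t.data)
    mask = t.data == out[segments]

    def back(g):
        return g[segments] * mask

    return Tensor(out, links=((t, back),))


def segment_min(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    return -segment_max(-t, segments, n_segments)
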
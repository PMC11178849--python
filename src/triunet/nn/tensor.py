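"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape-based engine sized for the volumetric regression networks in
this package: every value is a :class:`Tensor` wrapping a float32 ndarray,
operations record closures that propagate gradients, and
:meth:`Tensor.backward` walks the tape in reverse topological order.
Volumetric feature maps use a channels-last ``(N, D, H, W, C)`` layout so the
convolution lowers onto cache-friendly GEMMs.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


def grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextmanager
def no_grad():
    """Disable tape construction (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep at 3D-CNN scale
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free intermediate gradients once consumed
                node.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Wrap an op result, attaching the tape edge only when needed."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


# -- broadcasting-aware elementwise arithmetic --------------------------------

def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(-_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale_shift(x: Tensor, scale: float, shift: float) -> Tensor:
    """Affine map ``x * scale + shift`` with float constants."""
    out_data = x.data * np.float32(scale) + np.float32(shift)

    def backward(g):
        x.accumulate(g * np.float32(scale))

    return _make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        x.accumulate(g * (x.data > 0))

    return _make(out_data, (x,), backward)


def abs_(x: Tensor) -> Tensor:
    out_data = np.abs(x.data)

    def backward(g):
        x.accumulate(g * np.sign(x.data))

    return _make(out_data, (x,), backward)


def square(x: Tensor) -> Tensor:
    out_data = x.data * x.data

    def backward(g):
        x.accumulate(g * (2.0 * x.data))

    return _make(out_data, (x,), backward)


def mean_all(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.mean(), dtype=np.float32)
    n = x.data.size

    def backward(g):
        x.accumulate(np.broadcast_to(g / n, x.data.shape))

    return _make(out_data, (x,), backward)


def mean_axes(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    out_data = x.data.mean(axis=axes)
    n = int(np.prod([x.data.shape[a] for a in axes]))

    def backward(g):
        ge = np.expand_dims(g, axes) / n
        x.accumulate(np.broadcast_to(ge, x.data.shape).astype(np.float32))

    return _make(out_data, (x,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        x.accumulate(g.reshape(x.data.shape))

    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    out_data = x.data @ w.data

    def backward(g):
        x.accumulate(g @ w.data.T)
        w.accumulate(x.data.T @ g)

    return _make(out_data, (x, w), backward)
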
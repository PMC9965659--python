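"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's model components (convolutional sequence encoders,
graph-isomorphism layers, cross-attention, regression head) are built from
the small op set defined here.  Tensors carry float64 data; gradients are
accumulated on every node that participates in the graph, which is what the
atom-attribution code relies on to read gradients of *intermediate*
feature maps (not just leaf parameters).

Only the operations this package needs are implemented; each op defines its
own vector-Jacobian product and is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (evaluation mode) within the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus an optional backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff core --------------------------------------------------------

    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)

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

    # -- operator sugar -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getitem(self, key)

    # convenience reductions
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, *axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    # grads are never mutated in place, so the first contribution can be
    # stored by reference
    if t.requires_grad or t._parents:
        t.grad = g if t.grad is None else t.grad + g


def _node(data, parents, backward) -> Tensor:
    """Create a graph node; collapses to a constant when grads are off."""
    track = _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents)
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = False  # non-leaf; grads still accumulate via _parents
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- elementwise --------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, -g)

    return _node(-a.data, (a,), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _node(a.data / b.data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)

    def backward(g):
        _accumulate(a, g * p * a.data ** (p - 1))

    return _node(a.data**p, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, g / a.data)

    return _node(np.log(a.data), (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def backward(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


# -- linear algebra -----------------------------------------------------------


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.ndim < 2 or b.data.ndim < 2:
        raise ValueError("matmul requires tensors with at least 2 dimensions")

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accumulate(a, _unbroadcast(ga, a.data.shape))
        _accumulate(b, _unbroadcast(gb, b.data.shape))

    return _node(a.data @ b.data, (a, b), backward)


# -- reductions ---------------------------------------------------------------


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            grad = np.broadcast_to(g2, a.data.shape)
        _accumulate(a, np.ascontiguousarray(grad))

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis] if isinstance(axis, int) else int(
            np.prod([a.data.shape[ax] for ax in axis])
        )

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g / n, a.data.shape)
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            grad = np.broadcast_to(g2 / n, a.data.shape)
        _accumulate(a, np.ascontiguousarray(grad))

    return _node(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)


def tmax(a, axis=None, keepdims=False) -> Tensor:
    """Max reduction; ties route the gradient to the first maximal entry."""
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            mask = np.zeros_like(a.data)
            mask[np.unravel_index(np.argmax(a.data), a.data.shape)] = 1.0
            _accumulate(a, mask * g)
        else:
            idx = np.expand_dims(np.argmax(a.data, axis=axis), axis)
            mask = np.zeros_like(a.data)
            np.put_along_axis(mask, idx, 1.0, axis=axis)
            g2 = g if keepdims else np.expand_dims(g, axis)
            _accumulate(a, mask * g2)

    return _node(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * out_data).sum(axis=axis, keepdims=True)
        _accumulate(a, out_data * (g - inner))

    return _node(out_data, (a,), backward)


# -- shape manipulation -------------------------------------------------------


def reshape(a, *shape) -> Tensor:
    a = _as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    orig = a.data.shape

    def backward(g):
        _accumulate(a, g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a, *axes) -> Tensor:
    a = _as_tensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    if not axes or axes == (None,):
        axes = tuple(reversed(range(a.data.ndim)))
    inverse = np.argsort(axes)

    def backward(g):
        _accumulate(a, g.transpose(inverse))

    return _node(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def getitem(a, key) -> Tensor:
    """Basic (slice / integer) indexing."""
    a = _as_tensor(a)

    def backward(g):
        grad = np.zeros_like(a.data)
        grad[key] = g
        _accumulate(a, grad)

    return _node(a.data[key], (a,), backward)


def pad_axis(a, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad one axis (used for 'same' convolutions)."""
    a = _as_tensor(a)
    widths = [(0, 0)] * a.data.ndim
    widths[axis] = (before, after)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(before, before + a.data.shape[axis])
    sl = tuple(sl)

    def backward(g):
        _accumulate(a, g[sl])

    return _node(np.pad(a.data, widths), (a,), backward)


# -- gather / scatter ---------------------------------------------------------


def take(a, idx) -> Tensor:
    """Fancy indexing along axis 0 with an arbitrary-shape integer index."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        grad = np.zeros_like(a.data)
        np.add.at(grad, idx, g)
        _accumulate(a, grad)

    return _node(a.data[idx], (a,), backward)


def segment_sum(a, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of `a` into `num_segments` buckets given per-row segment ids."""
    a = _as_tensor(a)
    seg = np.asarray(segment_ids, dtype=np.intp)
    if seg.shape[0] != a.data.shape[0]:
        raise ValueError("segment ids must align with rows")
    out_data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, seg, a.data)

    def backward(g):
        _accumulate(a, g[seg])

    return _node(out_data, (a,), backward)


def masked_fill(a, mask, value: float) -> Tensor:
    """Replace entries where `mask` is True by `value` (constant w.r.t. grad)."""
    a = _as_tensor(a)
    mask = np.asarray(mask, dtype=bool)

    def backward(g):
        _accumulate(a, np.where(mask, 0.0, g))

    return _node(np.where(mask, value, a.data), (a,), backward)
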
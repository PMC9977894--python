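"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The capsule layers need gradients through voting (einsum), iterative routing
(softmax + weighted sums) and the squashing nonlinearities.  This module
provides exactly the operator set those layers use, on a :class:`Tensor`
wrapper around ``numpy.ndarray`` with a taped backward pass.

Design notes
------------
* Gradients are accumulated into ``Tensor.grad`` by a topological sweep.
* ``einsum`` is restricted to two operands where every input index appears in
  the output or the other operand (true for all uses here); its adjoints are
  themselves einsums.
* Patch extraction (``patches_hw``) is the im2col primitive behind
  convolutional capsule layers; its adjoint is an overlap-add scatter.
* Tensors are float32 by default; tests run float64 for finite-difference
  gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "neg", "exp", "log",
    "sqrt", "relu", "square", "tsum", "softmax", "einsum", "matmul",
    "reshape", "transpose", "concat", "getitem", "pad_hw", "patches_hw",
    "upsample2", "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, vjp callable grad_out -> grad_parent)
        self._parents = []

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad on non-scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for p, vjp in t._parents:
                if not (p.requires_grad or p._parents):
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents):
    out = Tensor(data)
    if _GRAD_ENABLED:
        out._parents = [(p, f) for p, f in parents
                        if p.requires_grad or p._parents]
    return out


def _unbroadcast(grad, shape):
    """Sum grad down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# Arithmetic ---------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data + b.data,
                 [(a, lambda g: _unbroadcast(g, a.data.shape)),
                  (b, lambda g: _unbroadcast(g, b.data.shape))])


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data - b.data,
                 [(a, lambda g: _unbroadcast(g, a.data.shape)),
                  (b, lambda g: _unbroadcast(-g, b.data.shape))])


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data * b.data,
                 [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
                  (b, lambda g: _unbroadcast(g * a.data, b.data.shape))])


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data
    return _node(out,
                 [(a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
                  (b, lambda g: _unbroadcast(-g * out / b.data, b.data.shape))])


def neg(a):
    a = as_tensor(a)
    return _node(-a.data, [(a, lambda g: -g)])


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return _node(out, [(a, lambda g: g * out)])


def log(a):
    a = as_tensor(a)
    return _node(np.log(a.data), [(a, lambda g: g / a.data)])


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _node(out, [(a, lambda g: g * (0.5 / out))])


def square(a):
    return mul(a, a)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _node(np.where(mask, a.data, 0), [(a, lambda g: g * mask)])


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return _node(out, [(a, vjp)])


def softmax(a, axis):
    """Numerically stable softmax; the max shift is treated as constant."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        inner = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - inner)

    return _node(out, [(a, vjp)])


# Structure ----------------------------------------------------------

def _parse_einsum(spec):
    lhs, rhs = spec.split("->")
    sa, sb = lhs.split(",")
    return sa, sb, rhs


def einsum(spec, a, b):
    """Two-operand einsum.  Every index of each operand must appear in the
    output or in the other operand (no internal traces)."""
    a, b = as_tensor(a), as_tensor(b)
    sa, sb, so = _parse_einsum(spec)
    out = np.einsum(spec, a.data, b.data, optimize=True)

    def vjp_a(g):
        return np.einsum(f"{so},{sb}->{sa}", g, b.data, optimize=True)

    def vjp_b(g):
        return np.einsum(f"{so},{sa}->{sb}", g, a.data, optimize=True)

    return _node(out, [(a, vjp_a), (b, vjp_b)])


def matmul(a, b):
    """Batched matrix product (..., M, K) @ (..., K, P) with identical batch
    dims (no broadcasting); routed through BLAS."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape[:-2] != b.data.shape[:-2]:
        raise ValueError("matmul batch dims must match exactly")
    out = a.data @ b.data

    def vjp_a(g):
        return g @ b.data.swapaxes(-1, -2)

    def vjp_b(g):
        return a.data.swapaxes(-1, -2) @ g

    return _node(out, [(a, vjp_a), (b, vjp_b)])


def reshape(a, shape):
    a = as_tensor(a)
    old = a.data.shape
    return _node(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def transpose(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)
    return _node(np.ascontiguousarray(a.data.transpose(axes)),
                 [(a, lambda g: g.transpose(inv))])


def concat(tensors, axis):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
        idx = [slice(None)] * out.ndim
        idx[axis] = slice(start, stop)
        idx = tuple(idx)
        parents.append((t, (lambda i: lambda g: g[i])(idx)))
    return _node(out, parents)


def getitem(a, idx):
    a = as_tensor(a)

    def vjp(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        return full

    return _node(a.data[idx], [(a, vjp)])


def pad_hw(a, ph, pw):
    """Zero-pad axes 1 and 2 of a (B, H, W, ...) tensor by ph/pw each side."""
    a = as_tensor(a)
    pads = [(0, 0), (ph, ph), (pw, pw)] + [(0, 0)] * (a.ndim - 3)
    out = np.pad(a.data, pads)
    sl = (slice(None), slice(ph, out.shape[1] - ph),
          slice(pw, out.shape[2] - pw))
    return _node(out, [(a, lambda g: np.ascontiguousarray(g[sl]))])


def patches_hw(a, kh, kw, sh, sw):
    """Extract (kh, kw) patches with stride (sh, sw) from a (B, H, W, ...)
    tensor -> (B, Ho, Wo, kh, kw, ...).  The im2col primitive; its adjoint is
    an overlap-add over kernel offsets."""
    a = as_tensor(a)
    x = a.data
    B, H, W = x.shape[:3]
    rest = x.shape[3:]
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # win: (B, H-kh+1, W-kw+1, ..., kh, kw) -> subsample stride, move kernel up
    win = win[:, ::sh, ::sw]
    src = list(range(win.ndim))
    order = src[:3] + src[-2:] + src[3:-2]
    out = np.ascontiguousarray(win.transpose(order))

    def vjp(g):
        gx = np.zeros_like(x)
        for i in range(kh):
            for j in range(kw):
                gx[:, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += g[:, :, :, i, j]
        return gx

    out = out.reshape((B, Ho, Wo, kh, kw) + rest)
    return _node(out, [(a, vjp)])


def upsample2(a):
    """Nearest-neighbour 2x upsampling of axes 1 and 2; adjoint sums each
    2x2 block."""
    a = as_tensor(a)
    out = np.repeat(np.repeat(a.data, 2, axis=1), 2, axis=2)

    def vjp(g):
        B, H2, W2 = g.shape[:3]
        rest = g.shape[3:]
        g = g.reshape((B, H2 // 2, 2, W2 // 2, 2) + rest)
        return g.sum(axis=(2, 4))

    return _node(out, [(a, vjp)])
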
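"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports higher-order derivatives: every vector-Jacobian product is itself
composed of the same primitive operations, so the graph produced by
:func:`grad` can be differentiated again.  This is exactly what variational
force matching needs — the training loss contains the model *forces*
(first derivatives w.r.t. coordinates), and its parameter gradient is
therefore a mixed second derivative.

Only the primitives required by the energy model are provided: elementwise
arithmetic, exp/log/sqrt/cos, a numerically stable softplus/sigmoid pair,
2-D matmul, axis reductions, reshape, fancy-index gather and scatter-add.
Shapes broadcast like numpy; gradients are un-broadcast by summation.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Var", "var", "grad",
    "exp", "log", "sqrt", "cos", "sin", "softplus", "sigmoid",
    "matmul", "vsum", "reshape", "take", "scatter_add", "segment_sum",
    "concat",
]


class Var:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        # parents: tuple of (Var, vjp) with vjp: Var -> Var
        self.parents = parents

    @property
    def shape(self):
        return self.data.shape

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return mul(self, Var(-1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __repr__(self):
        return f"Var(shape={self.data.shape})"


def _wrap(x):
    return x if isinstance(x, Var) else Var(x)


def var(x):
    """Wrap an array as a graph leaf."""
    return _wrap(x)


# -- broadcasting helper ---------------------------------------------------

def _unbroadcast(g: Var, shape) -> Var:
    """Sum ``g`` over axes that were broadcast to reach ``g.shape``."""
    if g.shape == tuple(shape):
        return g
    extra = len(g.shape) - len(shape)
    if extra > 0:
        g = vsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = vsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# -- primitives ------------------------------------------------------------

def add(a: Var, b: Var) -> Var:
    out = np.add(a.data, b.data)
    return Var(out, (
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ))


def sub(a: Var, b: Var) -> Var:
    out = np.subtract(a.data, b.data)
    return Var(out, (
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(mul(g, Var(-1.0)), b.shape)),
    ))


def mul(a: Var, b: Var) -> Var:
    out = np.multiply(a.data, b.data)
    return Var(out, (
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ))


def div(a: Var, b: Var) -> Var:
    out = np.divide(a.data, b.data)
    return Var(out, (
        (a, lambda g: _unbroadcast(div(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, div(mul(a, Var(-1.0)), mul(b, b))), b.shape)),
    ))


def power(a: Var, p: float) -> Var:
    p = float(p)
    out = np.power(a.data, p)
    return Var(out, (
        (a, lambda g: mul(g, mul(Var(p), power(a, p - 1.0))),),
    ))


def exp(a: Var) -> Var:
    out = np.exp(a.data)
    return Var(out, ((a, lambda g: mul(g, exp(a))),))


def log(a: Var) -> Var:
    out = np.log(a.data)
    return Var(out, ((a, lambda g: div(g, a)),))


def sqrt(a: Var) -> Var:
    out = np.sqrt(a.data)
    return Var(out, ((a, lambda g: div(g, mul(Var(2.0), sqrt(a)))),))


def cos(a: Var) -> Var:
    out = np.cos(a.data)
    return Var(out, ((a, lambda g: mul(g, mul(Var(-1.0), sin(a)))),))


def sin(a: Var) -> Var:
    out = np.sin(a.data)
    return Var(out, ((a, lambda g: mul(g, cos(a))),))


def sigmoid(a: Var) -> Var:
    # stable forward; vjp s(1-s) composed of primitives for higher order
    out = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                   np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    return Var(out, ((a, lambda g: mul(g, mul(sigmoid(a), sub(Var(1.0), sigmoid(a))))),))


def softplus(a: Var) -> Var:
    out = np.logaddexp(0.0, a.data)
    return Var(out, ((a, lambda g: mul(g, sigmoid(a))),))


def matmul(a: Var, b: Var) -> Var:
    """2-D matrix product (n,k) @ (k,m)."""
    out = a.data @ b.data
    return Var(out, (
        (a, lambda g: matmul(g, transpose(b))),
        (b, lambda g: matmul(transpose(a), g)),
    ))


def transpose(a: Var) -> Var:
    out = a.data.T
    return Var(out, ((a, lambda g: transpose(g)),))


def vsum(a: Var, axis=None, keepdims: bool = False) -> Var:
    out = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return mul(reshape(g, (1,) * a.data.ndim), Var(np.ones(a.shape)))
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.data.ndim for ax in axes)
        if keepdims:
            gk = g
        else:
            shp = list(a.shape)
            for ax in axes:
                shp[ax] = 1
            gk = reshape(g, tuple(shp))
        return mul(gk, Var(np.ones(a.shape)))

    return Var(out, ((a, vjp),))


def reshape(a: Var, shape) -> Var:
    shape = tuple(shape)
    out = a.data.reshape(shape)
    return Var(out, ((a, lambda g: reshape(g, a.shape)),))


def take(a: Var, idx, axis: int = 0) -> Var:
    """Gather rows ``a[idx]`` along ``axis`` (axis 0 only)."""
    if axis != 0:
        raise NotImplementedError("take supports axis=0")
    idx = np.asarray(idx, dtype=np.intp)
    out = a.data[idx]
    n = a.shape[0]
    return Var(out, ((a, lambda g: scatter_add(g, idx, n)),))


def segment_sum(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Sum rows of ``values`` into ``n`` output rows at positions ``idx``.

    Equivalent to ``np.add.at`` on zeros but far faster: sorts once and
    reduces contiguous segments.
    """
    out = np.zeros((n,) + values.shape[1:])
    if idx.size == 0:
        return out
    if np.all(idx[1:] >= idx[:-1]):
        idx_s, vals = idx, values
    else:
        order = np.argsort(idx, kind="stable")
        idx_s, vals = idx[order], values[order]
    starts = np.r_[0, np.flatnonzero(np.diff(idx_s)) + 1]
    out[idx_s[starts]] = np.add.reduceat(vals, starts, axis=0)
    return out


def scatter_add(src: Var, idx, n: int) -> Var:
    """Sum rows of ``src`` into ``n`` output rows at positions ``idx``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = segment_sum(src.data, idx, n)
    return Var(out, ((src, lambda g: take(g, idx)),))


def concat(parts, axis: int = 0) -> Var:
    parts = [_wrap(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    vjps = []
    start = 0
    for p in parts:
        n = p.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(start, start + n)
        sl = tuple(sl)

        def vjp(g, sl=sl):
            return _slice(g, sl)

        vjps.append((p, vjp))
        start += n
    return Var(out, tuple(vjps))


def _slice(a: Var, sl) -> Var:
    out = a.data[sl]

    return Var(out, ((a, lambda g: _unslice(g, a.shape, sl)),))


def _unslice(g: Var, shape, sl) -> Var:
    out = np.zeros(shape)
    out[sl] = g.data
    return Var(out, ((g, lambda gg: _slice(gg, sl)),))


# -- reverse pass ----------------------------------------------------------

def _toposort(root: Var):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(output: Var, inputs, seed: Var | None = None):
    """Gradients of scalar ``output`` w.r.t. each Var in ``inputs``.

    Returns Vars, so the result can be differentiated again.  ``seed``
    overrides the initial adjoint (defaults to ones of output's shape).
    """
    order = _toposort(output)
    adj: dict[int, Var] = {id(output): seed if seed is not None else Var(np.ones(output.shape))}
    for node in reversed(order):
        g = adj.get(id(node))
        if g is None:
            continue
        for parent, vjp in node.parents:
            pg = vjp(g)
            prev = adj.get(id(parent))
            adj[id(parent)] = pg if prev is None else add(prev, pg)
    out = []
    for x in inputs:
        gx = adj.get(id(x))
        out.append(gx if gx is not None else Var(np.zeros(x.shape)))
    return out
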
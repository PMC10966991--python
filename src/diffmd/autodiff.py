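"""Tape-based reverse-mode automatic differentiation over numpy arrays.

Supports the small set of array primitives needed to express molecular-mechanics
energies and a Langevin integrator step. Every vector-Jacobian product (VJP) is
itself written in terms of these primitives, so adjoints propagated through a
recorded graph may themselves be :class:`Var` nodes — this is what makes
higher-order differentiation work: forces obtained as the reverse pass of an
energy graph remain differentiable with respect to coordinates and parameters.

Conventions
-----------
* A :class:`Var` wraps an ``ndarray`` (or scalar) ``value`` and a tuple of
  ``(parent, vjp)`` pairs. Operations on plain arrays short-circuit to numpy.
* Index keys, boolean masks and shapes are treated as constants.
* ``maximum``/``where``/``abs`` use value-based masks; at their measure-zero
  kinks the derivative of the selected branch is returned.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var", "val", "is_var", "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "tanh", "sin", "cos", "arccos", "arctan2",
    "absolute", "maximum", "minimum", "where", "asum", "reshape", "getitem",
    "scatter_add", "stack_last", "backward", "grad", "norm", "dot",
]


class Var:
    """A node in the computation graph."""

    __slots__ = ("value", "parents")

    # make ndarray <op> Var defer to Var's reflected operators
    __array_ufunc__ = None

    def __init__(self, value, parents=()):
        self.value = np.asarray(value)
        self.parents = parents

    # -- operator sugar -------------------------------------------------
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

    def __pow__(self, c):
        return power(self, c)

    def __getitem__(self, key):
        return getitem(self, key)

    @property
    def shape(self):
        return self.value.shape

    @property
    def dtype(self):
        return self.value.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.value.shape}, dtype={self.value.dtype})"


def val(x):
    """Underlying ndarray/scalar of ``x`` whether or not it is a Var."""
    return x.value if isinstance(x, Var) else x


def is_var(x):
    return isinstance(x, Var)


def _shape(x):
    return np.shape(val(x))


def unbroadcast(g, shape):
    """Reduce ``g`` (Var or array) back to ``shape`` after numpy broadcasting."""
    gshape = _shape(g)
    if gshape == tuple(shape):
        return g
    while len(_shape(g)) > len(shape):
        g = asum(g, axis=0)
    for i, s in enumerate(shape):
        if s == 1 and _shape(g)[i] != 1:
            g = asum(g, axis=i, keepdims=True)
    return g


_grad_enabled = [True]


class no_grad:
    """Context in which operations on Vars return plain values (no tape)."""

    def __enter__(self):
        self._prev = _grad_enabled[0]
        _grad_enabled[0] = False

    def __exit__(self, *exc):
        _grad_enabled[0] = self._prev


def _make(value, parents):
    if not _grad_enabled[0]:
        return value
    if any(isinstance(p, Var) for p, _ in parents):
        return Var(value, tuple((p, f) for p, f in parents if isinstance(p, Var)))
    return value


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def _binary(a, b, out, vjp_a, vjp_b):
    """Record a binary op; skip unbroadcast when operand shape == out shape."""
    so = np.shape(out)
    parents = []
    if type(a) is Var:
        sa = np.shape(a.value)
        if sa == so:
            parents.append((a, vjp_a))
        else:
            parents.append((a, lambda g: unbroadcast(vjp_a(g), sa)))
    if type(b) is Var:
        sb = np.shape(b.value)
        if sb == so:
            parents.append((b, vjp_b))
        else:
            parents.append((b, lambda g: unbroadcast(vjp_b(g), sb)))
    return Var(out, tuple(parents))


def add(a, b):
    out = (a.value if type(a) is Var else a) + (b.value if type(b) is Var else b)
    if not _grad_enabled[0] or not (type(a) is Var or type(b) is Var):
        return out
    return _binary(a, b, out, lambda g: g, lambda g: g)


def sub(a, b):
    out = (a.value if type(a) is Var else a) - (b.value if type(b) is Var else b)
    if not _grad_enabled[0] or not (type(a) is Var or type(b) is Var):
        return out
    return _binary(a, b, out, lambda g: g, lambda g: neg(g))


def mul(a, b):
    out = (a.value if type(a) is Var else a) * (b.value if type(b) is Var else b)
    if not _grad_enabled[0] or not (type(a) is Var or type(b) is Var):
        return out
    return _binary(a, b, out, lambda g: mul(g, b), lambda g: mul(g, a))


def div(a, b):
    out = (a.value if type(a) is Var else a) / (b.value if type(b) is Var else b)
    if not _grad_enabled[0] or not (type(a) is Var or type(b) is Var):
        return out
    return _binary(a, b, out, lambda g: div(g, b),
                   lambda g: neg(div(mul(g, a), mul(b, b))))


def neg(a):
    if type(a) is not Var:
        return -a
    if not _grad_enabled[0]:
        return -a.value
    return Var(-a.value, ((a, neg),))


def power(a, c):
    """``a ** c`` for a constant (non-Var) exponent ``c``."""
    av = val(a)
    out = av ** c
    if not isinstance(a, Var):
        return out
    return _make(out, [(a, lambda g: mul(g, mul(c, power(a, c - 1))))])


def exp(a):
    # VJPs recompute from ``a`` rather than capturing the output Var: parents
    # must only point backwards so graphs stay acyclic and refcount-collected
    if not isinstance(a, Var):
        return np.exp(a)
    return _make(np.exp(a.value), [(a, lambda g: mul(g, exp(a)))])


def log(a):
    if not isinstance(a, Var):
        return np.log(a)
    return _make(np.log(a.value), [(a, lambda g: div(g, a))])


def sqrt(a):
    if not isinstance(a, Var):
        return np.sqrt(a)
    return _make(np.sqrt(a.value), [(a, lambda g: div(g, mul(2.0, sqrt(a))))])


def tanh(a):
    if not isinstance(a, Var):
        return np.tanh(a)

    def vjp(g):
        t = tanh(a)
        return mul(g, sub(1.0, mul(t, t)))

    return _make(np.tanh(a.value), [(a, vjp)])


def sin(a):
    if not isinstance(a, Var):
        return np.sin(a)
    return _make(np.sin(a.value), [(a, lambda g: mul(g, cos(a)))])


def cos(a):
    if not isinstance(a, Var):
        return np.cos(a)
    return _make(np.cos(a.value), [(a, lambda g: neg(mul(g, sin(a))))])


def arccos(a):
    if not isinstance(a, Var):
        return np.arccos(a)
    return _make(np.arccos(a.value), [
        (a, lambda g: neg(div(g, sqrt(sub(1.0, mul(a, a)))))),
    ])


def arctan2(y, x):
    out = np.arctan2(val(y), val(x))
    if not (isinstance(y, Var) or isinstance(x, Var)):
        return out
    sy, sx = _shape(y), _shape(x)

    def denom():
        return add(mul(x, x), mul(y, y))

    return _make(out, [
        (y, lambda g: unbroadcast(div(mul(g, x), denom()), sy)),
        (x, lambda g: unbroadcast(neg(div(mul(g, y), denom())), sx)),
    ])


def absolute(a):
    if not isinstance(a, Var):
        return np.abs(a)
    s = np.sign(a.value)
    return _make(np.abs(a.value), [(a, lambda g: mul(g, s))])


def maximum(a, b):
    av, bv = val(a), val(b)
    out = np.maximum(av, bv)
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return out
    mask = av >= bv
    sa, sb = _shape(a), _shape(b)
    return _make(out, [
        (a, lambda g: unbroadcast(where(mask, g, 0.0), sa)),
        (b, lambda g: unbroadcast(where(mask, 0.0, g), sb)),
    ])


def minimum(a, b):
    av, bv = val(a), val(b)
    out = np.minimum(av, bv)
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return out
    mask = av <= bv
    sa, sb = _shape(a), _shape(b)
    return _make(out, [
        (a, lambda g: unbroadcast(where(mask, g, 0.0), sa)),
        (b, lambda g: unbroadcast(where(mask, 0.0, g), sb)),
    ])


def where(cond, a, b):
    """Select with a constant boolean mask ``cond``."""
    cond = np.asarray(val(cond), dtype=bool)
    out = np.where(cond, val(a), val(b))
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return out
    sa, sb = _shape(a), _shape(b)
    return _make(out, [
        (a, lambda g: unbroadcast(where(cond, g, 0.0), sa)),
        (b, lambda g: unbroadcast(where(cond, 0.0, g), sb)),
    ])


# ---------------------------------------------------------------------------
# shape / reduction primitives
# ---------------------------------------------------------------------------

def asum(a, axis=None, keepdims=False):
    av = val(a)
    out = np.sum(av, axis=axis, keepdims=keepdims)
    if not isinstance(a, Var):
        return out
    in_shape = av.shape

    def vjp(g):
        if axis is not None and not keepdims:
            kd = list(in_shape)
            axes = (axis,) if np.isscalar(axis) else axis
            for ax in axes:
                kd[ax] = 1
            g = reshape(g, tuple(kd))
        return broadcast_to(g, in_shape)

    return _make(out, [(a, vjp)])


def broadcast_to(a, shape):
    av = val(a)
    out = np.broadcast_to(av, shape)
    if not isinstance(a, Var):
        return out
    sa = av.shape
    return _make(out, [(a, lambda g: unbroadcast(g, sa))])


def reshape(a, shape):
    av = val(a)
    out = np.reshape(av, shape)
    if not isinstance(a, Var):
        return out
    sa = av.shape
    return _make(out, [(a, lambda g: reshape(g, sa))])


def getitem(a, key):
    av = val(a)
    out = av[key]
    if not isinstance(a, Var):
        return out
    sa = av.shape
    dt = av.dtype
    return _make(out, [(a, lambda g: scatter_add(g, key, sa, dt))])


def scatter_add(g, key, shape, dtype=None):
    """Zeros of ``shape`` with ``g`` added at ``key`` (adjoint of getitem)."""
    gv = np.asarray(val(g))
    dt = dtype if dtype is not None else gv.dtype
    if (isinstance(key, np.ndarray) and key.ndim == 1 and
            key.dtype.kind in "iu" and gv.ndim == 1 and len(shape) == 1):
        z = np.bincount(key, weights=gv, minlength=shape[0]).astype(dt, copy=False)
    elif isinstance(key, (slice, int)) or (isinstance(key, tuple) and
            all(isinstance(k, (slice, int)) for k in key)):
        # basic indexing selects disjoint positions: plain += is exact
        z = np.zeros(shape, dtype=dt)
        z[key] += gv
    else:
        z = np.zeros(shape, dtype=dt)
        np.add.at(z, key, gv)
    if not isinstance(g, Var):
        return z
    return _make(z, [(g, lambda gg: getitem(gg, key))])


def spmatmul(S, a, ST):
    """Constant sparse matrix times (possibly Var) dense array.

    ``ST`` is the precomputed transpose used by the VJP.
    """
    av = val(a)
    out = S @ av
    if not isinstance(a, Var):
        return out
    return _make(out, [(a, lambda g: spmatmul(ST, g, S))])


def concat(arrs, axis=0):
    """Concatenate along an existing axis."""
    vals = [val(a) for a in arrs]
    out = np.concatenate(vals, axis=axis)
    if not any(isinstance(a, Var) for a in arrs):
        return out
    parents = []
    start = 0
    for a, v in zip(arrs, vals):
        size = v.shape[axis]
        if isinstance(a, Var):
            key = (slice(None),) * axis + (slice(start, start + size),)
            parents.append((a, (lambda k: lambda g: getitem(g, k))(key)))
        start += size
    return _make(out, parents)


def stack_last(arrs):
    """Stack a list of equally-shaped arrays along a new trailing axis."""
    vals = [val(a) for a in arrs]
    out = np.stack(vals, axis=-1)
    if not any(isinstance(a, Var) for a in arrs):
        return out
    parents = []
    for i, a in enumerate(arrs):
        if isinstance(a, Var):
            parents.append((a, (lambda i_: lambda g: getitem(g, (Ellipsis, i_)))(i)))
    return _make(out, parents)


# ---------------------------------------------------------------------------
# convenience compositions
# ---------------------------------------------------------------------------

def matmul(a, b):
    out = val(a) @ val(b)
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return out
    return _make(out, [
        (a, lambda g: matmul(g, transpose(b))),
        (b, lambda g: matmul(transpose(a), g)),
    ])


def transpose(a):
    if not isinstance(a, Var):
        return np.swapaxes(a, -1, -2)
    return _make(np.swapaxes(a.value, -1, -2), [(a, lambda g: transpose(g))])


def dot(a, b):
    return asum(mul(a, b))


def norm(a):
    return sqrt(asum(mul(a, a)))


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------

def _topo_order(root, stop_ids=()):
    order = []
    visited = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        if id(node) in stop_ids:
            continue
        for p, _ in node.parents:
            if isinstance(p, Var) and id(p) not in visited:
                stack.append((p, False))
    return order  # leaves first, root last


def backward(root, wrt, seed=None, taped=True, stop=()):
    """Adjoints of scalar ``root`` with respect to each Var in ``wrt``.

    With ``taped=True`` (default) returned adjoints are Vars when the VJP
    chain touches recorded Vars (enabling grad-of-grad); call :func:`val` on
    them if only values are needed. ``taped=False`` runs the reverse pass
    under :class:`no_grad` and returns plain arrays — cheaper when only the
    first-order gradient value is wanted. A ``wrt`` entry the graph does not
    reach yields ``None``.
    """
    if not isinstance(root, Var):
        return [None for _ in wrt]
    stop_ids = {id(s) for s in stop}
    order = _topo_order(root, stop_ids)
    wrt_ids = {id(w): i for i, w in enumerate(wrt)}
    results = [None] * len(wrt)
    if seed is None:
        seed = np.asarray(1.0, dtype=root.value.dtype)
    adj = {id(root): seed}
    ctx = no_grad() if not taped else None
    if ctx is not None:
        ctx.__enter__()
    try:
        for node in reversed(order):
            g = adj.pop(id(node), None)
            if g is None:
                continue
            i = wrt_ids.get(id(node))
            if i is not None:
                results[i] = g
            if id(node) in stop_ids:
                continue
            for p, vjp in node.parents:
                if not isinstance(p, Var):
                    continue
                pg = vjp(g)
                cur = adj.get(id(p))
                adj[id(p)] = pg if cur is None else add(cur, pg)
    finally:
        if ctx is not None:
            ctx.__exit__()
    return results


def grad(root, wrt, seed=None, taped=True):
    """Plain-ndarray gradients of scalar ``root`` w.r.t. Vars in ``wrt``."""
    out = backward(root, wrt, seed=seed, taped=taped)
    res = []
    for w, g in zip(wrt, out):
        if g is None:
            res.append(np.zeros(np.shape(w.value), dtype=w.value.dtype))
        else:
            g = val(g)
            res.append(np.array(np.broadcast_to(g, np.shape(w.value)), dtype=w.value.dtype))
    return res
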
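"""Minimal reverse-mode automatic differentiation over numpy arrays.

The likelihood targets in this package must expose exact gradients of a
scalar loss with respect to atomic coordinates and MSA-profile bias
parameters.  Rather than hand-deriving the full chain (structure-factor
summation -> per-bin normalization -> Rice/Woolfson log-likelihood), the
chain is built from a small set of differentiable primitives on a
:class:`Var` tape.  Every op also accepts plain ndarrays, in which case it
evaluates eagerly with numpy and records nothing; the likelihood code is
therefore written once and used both for fast numeric evaluation (e.g.
inside Newton iterations) and for gradient computation.

Only what the pipeline needs is implemented: elementwise arithmetic with
broadcasting, exp/log/sqrt/trig, 2-D matmul, reductions, gather/scatter by
index, segment sums (per-resolution-bin statistics), and the two special
functions log I0 and log cosh used by the acentric/centric likelihoods.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Var", "value", "is_var", "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "square", "sin", "cos", "tanh", "matmul",
    "sum_", "take", "segment_sum", "log_i0", "log_cosh", "grad",
]


def value(x):
    """Underlying ndarray (or scalar) of ``x`` whether or not it is a Var."""
    return x.value if isinstance(x, Var) else x


def is_var(x) -> bool:
    return isinstance(x, Var)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Var:
    """Node in the computation graph: a value plus vjp edges to parents."""

    __slots__ = ("value", "grad", "_parents")

    def __init__(self, val, parents=()):
        self.value = np.asarray(val, dtype=np.float64)
        self.grad = None
        self._parents = parents  # tuple of (Var, vjp callable)

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self) -> np.ndarray:
        return self.value

    def backward(self, seed=None):
        """Accumulate d(self)/d(leaf) into ``.grad`` of every ancestor."""
        topo: list[Var] = []
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
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value) if seed is None else np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                # rebinding (never in-place mutation) makes aliasing safe
                if parent.grad is None:
                    parent.grad = np.asarray(pg, dtype=np.float64)
                else:
                    parent.grad = parent.grad + pg

    # -- operator sugar -------------------------------------------------
    def __add__(self, o):
        return add(self, o)

    __radd__ = __add__

    def __mul__(self, o):
        return mul(self, o)

    __rmul__ = __mul__

    def __sub__(self, o):
        return sub(self, o)

    def __rsub__(self, o):
        return sub(o, self)

    def __truediv__(self, o):
        return div(self, o)

    def __rtruediv__(self, o):
        return div(o, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, o):
        return matmul(self, o)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None):
        return sum_(self, axis=axis)

    @property
    def T(self):
        return transpose(self)

    def __repr__(self):
        return f"Var(shape={self.value.shape})"


def _make(val, parents):
    parents = tuple((p, v) for p, v in parents if isinstance(p, Var))
    if not parents:
        return val  # all inputs constant: stay out of the graph
    return Var(val, parents)


# -- elementwise binary ops ---------------------------------------------

def add(a, b):
    av, bv = value(a), value(b)
    out = av + bv
    if not (is_var(a) or is_var(b)):
        return out
    av, bv = np.asarray(av), np.asarray(bv)
    return _make(out, [
        (a, lambda g: _unbroadcast(g, av.shape)),
        (b, lambda g: _unbroadcast(g, bv.shape)),
    ])


def sub(a, b):
    av, bv = value(a), value(b)
    out = av - bv
    if not (is_var(a) or is_var(b)):
        return out
    av, bv = np.asarray(av), np.asarray(bv)
    return _make(out, [
        (a, lambda g: _unbroadcast(g, av.shape)),
        (b, lambda g: _unbroadcast(-g, bv.shape)),
    ])


def mul(a, b):
    av, bv = value(a), value(b)
    out = av * bv
    if not (is_var(a) or is_var(b)):
        return out
    av, bv = np.asarray(av), np.asarray(bv)
    return _make(out, [
        (a, lambda g: _unbroadcast(g * bv, av.shape)),
        (b, lambda g: _unbroadcast(g * av, bv.shape)),
    ])


def div(a, b):
    av, bv = value(a), value(b)
    out = av / bv
    if not (is_var(a) or is_var(b)):
        return out
    av, bv = np.asarray(av), np.asarray(bv)
    return _make(out, [
        (a, lambda g: _unbroadcast(g / bv, av.shape)),
        (b, lambda g: _unbroadcast(-g * av / (bv * bv), bv.shape)),
    ])


def neg(a):
    if not is_var(a):
        return -a
    return _make(-a.value, [(a, lambda g: -g)])


def power(a, p):
    """a**p for a constant (non-Var) exponent p."""
    av = value(a)
    out = av ** p
    if not is_var(a):
        return out
    return _make(out, [(a, lambda g: g * p * av ** (p - 1))])


# -- elementwise unary ops ----------------------------------------------

def _unary(a, f, dfdx):
    av = value(a)
    out = f(av)
    if not is_var(a):
        return out
    return _make(out, [(a, lambda g: g * dfdx(av, out))])


def exp(a):
    return _unary(a, np.exp, lambda x, y: y)


def log(a):
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def sqrt(a):
    return _unary(a, np.sqrt, lambda x, y: 0.5 / y)


def square(a):
    return _unary(a, np.square, lambda x, y: 2.0 * x)


def sin(a):
    return _unary(a, np.sin, lambda x, y: np.cos(x))


def cos(a):
    return _unary(a, np.cos, lambda x, y: -np.sin(x))


def sincos(a):
    """(sin a, cos a) with each value reused in the other's derivative."""
    av = value(a)
    s, c = np.sin(av), np.cos(av)
    if not is_var(a):
        return s, c
    return (_make(s, [(a, lambda g: g * c)]),
            _make(c, [(a, lambda g: -g * s)]))


def tanh(a):
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def log_i0(a):
    """ln I0(x), stable for large |x|; d/dx = I1(x)/I0(x)."""
    def f(x):
        return np.log(_sp.i0e(x)) + np.abs(x)

    def d(x, y):
        return _sp.i1e(x) / _sp.i0e(x)  # i1e is odd, i0e even: correct sign

    return _unary(a, f, d)


def log_cosh(a):
    """ln cosh(x), stable for large |x|; d/dx = tanh(x)."""
    def f(x):
        ax = np.abs(x)
        return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)

    return _unary(a, f, lambda x, y: np.tanh(x))


# -- linear algebra / shaping -------------------------------------------

def matmul(a, b):
    av, bv = value(a), value(b)
    out = av @ bv
    if not (is_var(a) or is_var(b)):
        return out
    return _make(out, [
        (a, lambda g: g @ np.swapaxes(bv, -1, -2)),
        (b, lambda g: np.swapaxes(av, -1, -2) @ g),
    ])


def transpose(a, axes=None):
    av = value(a)
    out = np.transpose(av, axes)
    if not is_var(a):
        return out
    inv = None if axes is None else np.argsort(axes)
    return _make(out, [(a, lambda g: np.transpose(g, inv))])


def reshape(a, shape):
    av = value(a)
    out = np.reshape(av, shape)
    if not is_var(a):
        return out
    orig = av.shape
    return _make(out, [(a, lambda g: np.reshape(g, orig))])


def sum_(a, axis=None):
    av = value(a)
    out = np.sum(av, axis=axis)
    if not is_var(a):
        return out
    shape = av.shape

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, shape)
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        g2 = np.expand_dims(g, tuple(ax % len(shape) for ax in axes))
        return np.broadcast_to(g2, shape)

    return _make(out, [(a, vjp)])


def take(a, idx):
    """Gather a[idx] (integer array, boolean mask, or basic slicing)."""
    av = value(a)
    out = av[idx]
    if not is_var(a):
        return out
    shape = av.shape

    def vjp(g):
        z = np.zeros(shape, dtype=np.float64)
        if isinstance(idx, np.ndarray) and idx.dtype != bool:
            np.add.at(z, idx, g)
        else:
            z[idx] = z[idx] + g
        return z

    return _make(out, [(a, vjp)])


def segment_sum(a, seg_id: np.ndarray, num: int):
    """out[k] = sum of a[i] over i with seg_id[i] == k (1-D input)."""
    av = value(a)
    out = np.bincount(seg_id, weights=av, minlength=num)
    if not is_var(a):
        return out
    return _make(out, [(a, lambda g: g[seg_id])])


def put(base: np.ndarray, idx, a):
    """Copy of constant ``base`` with rows ``idx`` replaced by ``a``."""
    out = np.array(base, dtype=np.float64)
    out[idx] = value(a)
    if not is_var(a):
        return out
    return _make(out, [(a, lambda g: g[idx])])


def grad(f, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and gradient of scalar function ``f`` at ndarray ``x``."""
    xv = Var(x)
    out = f(xv)
    out.backward()
    return float(out.value), xv.grad
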
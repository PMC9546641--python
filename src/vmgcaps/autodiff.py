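"""Minimal reverse-mode automatic differentiation on numpy arrays.

The capsule layers in this package differentiate through digamma functions,
log-determinants and iterated Bayesian updates, so the set of primitives is
small but slightly unusual (``digamma``/``gammaln`` carry their polygamma
derivatives). Tensors wrap float64 numpy arrays; a computation graph is built
eagerly and traversed in reverse topological order by :meth:`Tensor.backward`.

Graph construction is skipped entirely inside :func:`no_grad` or when no input
requires gradients, so inference runs at plain-numpy cost.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special

__all__ = [
    "Tensor",
    "Parameter",
    "astensor",
    "no_grad",
    "add", "mul", "matmul", "einsum", "exp", "log", "sqrt", "sigmoid",
    "relu", "digamma", "gammaln", "logsumexp", "softmax", "pad2d",
    "take_last", "concat", "Adam",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / sampling passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def _accum(self, g: np.ndarray) -> None:
        # grads are only ever rebound (never mutated in place), so sharing
        # the incoming array is safe and avoids large copies
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, astensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -astensor(other))

    def __rsub__(self, other):
        return add(astensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(astensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, float(p))

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that is optimized during training."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[Tensor], Callable[[], None]]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- arithmetic ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return run
    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return run
    return _node(a.data * b.data, (a, b), bw)


def power(a: Tensor, p: float) -> Tensor:
    def bw(out):
        def run():
            if a.requires_grad:
                a._accum(out.grad * p * a.data ** (p - 1.0))
        return run
    return _node(a.data ** p, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))
        return run
    return _node(np.matmul(a.data, b.data), (a, b), bw)


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum. Every index of each input must appear in the
    output or in the other input (plain tensor contractions only)."""
    lhs, out_spec = spec.replace(" ", "").split("->")
    sa, sb = lhs.split(",")
    if len(set(sa)) != len(sa) or len(set(sb)) != len(sb):
        raise ValueError("einsum: repeated index within one operand")
    for i in sa:
        if i not in out_spec and i not in sb:
            raise ValueError(f"einsum: index {i!r} unsupported for backprop")
    for i in sb:
        if i not in out_spec and i not in sa:
            raise ValueError(f"einsum: index {i!r} unsupported for backprop")

    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad:
                a._accum(np.einsum(f"{out_spec},{sb}->{sa}", g, b.data))
            if b.requires_grad:
                b._accum(np.einsum(f"{out_spec},{sa}->{sb}", g, a.data))
        return run
    return _node(np.einsum(spec, a.data, b.data), (a, b), bw)


# -- elementwise nonlinearities ------------------------------------------

def exp(a: Tensor) -> Tensor:
    d = np.exp(a.data)

    def bw(out):
        def run():
            a._accum(out.grad * d)
        return run
    return _node(d, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(out):
        def run():
            a._accum(out.grad / a.data)
        return run
    return _node(np.log(a.data), (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    d = np.sqrt(a.data)

    def bw(out):
        def run():
            a._accum(out.grad * 0.5 / d)
        return run
    return _node(d, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    d = special.expit(a.data)

    def bw(out):
        def run():
            a._accum(out.grad * d * (1.0 - d))
        return run
    return _node(d, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(out):
        def run():
            a._accum(out.grad * mask)
        return run
    return _node(a.data * mask, (a,), bw)


def digamma(a: Tensor) -> Tensor:
    def bw(out):
        def run():
            a._accum(out.grad * special.polygamma(1, a.data))
        return run
    return _node(special.digamma(a.data), (a,), bw)


def gammaln(a: Tensor) -> Tensor:
    def bw(out):
        def run():
            a._accum(out.grad * special.digamma(a.data))
        return run
    return _node(special.gammaln(a.data), (a,), bw)


# -- reductions / shape ---------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))
        return run
    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def reshape(a: Tensor, shape) -> Tensor:
    def bw(out):
        def run():
            a._accum(out.grad.reshape(a.data.shape))
        return run
    return _node(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def bw(out):
        def run():
            a._accum(out.grad.transpose(inv))
        return run
    return _node(a.data.transpose(axes), (a,), bw)


def getitem(a: Tensor, idx) -> Tensor:
    def bw(out):
        def run():
            g = np.zeros_like(a.data)
            np.add.at(g, idx, out.grad)
            a._accum(g)
        return run
    return _node(a.data[idx], (a,), bw)


def take_last(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather along the last axis with a 1-D integer index (may repeat)."""
    idx = np.asarray(idx)
    d = a.data[..., idx]

    def bw(out):
        def run():
            lead = int(np.prod(a.data.shape[:-1], dtype=int))
            g2 = out.grad.reshape(lead, idx.size)
            gx = np.zeros((lead, a.data.shape[-1]))
            np.add.at(gx, (np.arange(lead)[:, None], idx[None, :]), g2)
            a._accum(gx.reshape(a.data.shape))
        return run
    return _node(d, (a,), bw)


def pad2d(a: Tensor, p: int) -> Tensor:
    """Zero-pad the last two axes by ``p`` on each side."""
    if p == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(p, p), (p, p)]
    sl = tuple([slice(None)] * (a.ndim - 2) + [slice(p, -p), slice(p, -p)])

    def bw(out):
        def run():
            a._accum(out.grad[sl])
        return run
    return _node(np.pad(a.data, width), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(out.grad[tuple(sl)])
        return run
    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, bw)


def logsumexp(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along one axis (graph-safe)."""
    m = np.max(a.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = a - Tensor(m)
    out = log(tsum(exp(shifted), axis=axis, keepdims=True)) + Tensor(m)
    if not keepdims:
        out = reshape(out, tuple(np.delete(out.shape, axis)))
    return out


def softmax(a: Tensor, axis: int) -> Tensor:
    return exp(a - logsumexp(a, axis=axis, keepdims=True))


# -- fused routing kernels -------------------------------------------------
# The routing E/M steps dominate training cost; these three primitives fuse
# the largest (M, n, K, D) elementwise chains into single graph nodes with
# analytic backward passes.

def weighted_sq_dist(v: Tensor, m: Tensor, w: Tensor) -> Tensor:
    """sum_d w_kd (v_nkd - m_kd)^2: v (M,n,K,D), m/w (M,K,D) -> (M,n,K)."""
    diff = v.data - m.data[:, None]

    def bw(out):
        def run():
            g = out.grad
            if v.requires_grad or m.requires_grad:
                gv = (2.0 * g)[..., None] * diff * w.data[:, None]
                if v.requires_grad:
                    v._accum(gv)
                if m.requires_grad:
                    m._accum(-gv.sum(axis=1))
            if w.requires_grad:
                w._accum(np.einsum("ank,ankd->akd", g, diff * diff))
        return run
    return _node(np.einsum("ankd,akd->ank", diff * diff, w.data),
                 (v, m, w), bw)


def weighted_moment(wt: Tensor, v: Tensor, power: int = 1) -> Tensor:
    """sum_n wt_nk v_nkd^power: wt (M,n,K), v (M,n,K,D) -> (M,K,D)."""
    vp = v.data if power == 1 else v.data ** power

    def bw(out):
        def run():
            g = out.grad
            if wt.requires_grad:
                wt._accum(np.einsum("akd,ankd->ank", g, vp))
            if v.requires_grad:
                gv = g[:, None] * wt.data[..., None]
                if power != 1:
                    gv = gv * (power * v.data ** (power - 1))
                v._accum(gv)
        return run
    return _node(np.einsum("ank,ankd->akd", wt.data, vp), (wt, v), bw)


def weighted_sqdiff_sum(wt: Tensor, v: Tensor, m: Tensor) -> Tensor:
    """sum_n wt_nk (v_nkd - m_kd)^2: -> (M,K,D)."""
    diff = v.data - m.data[:, None]

    def bw(out):
        def run():
            g = out.grad
            if wt.requires_grad:
                wt._accum(np.einsum("akd,ankd->ank", g, diff * diff))
            if v.requires_grad or m.requires_grad:
                gv = 2.0 * g[:, None] * wt.data[..., None] * diff
                if v.requires_grad:
                    v._accum(gv)
                if m.requires_grad:
                    m._accum(-gv.sum(axis=1))
        return run
    return _node(np.einsum("ank,ankd->akd", wt.data, diff * diff),
                 (wt, v, m), bw)


# -- optimizer ------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of :class:`Parameter`."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
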
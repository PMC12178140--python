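"""Reverse-mode automatic differentiation on dense numpy arrays.

A small tensor engine powering the trainable parts of the model: the
graph encoder, the KAN/MLP decoders and the edge-scoring head.  It
implements exactly the primitives those components need — broadcasting
arithmetic, matmul, a restricted two-operand einsum, reductions, row
gather/slicing, concatenation and a few smooth nonlinearities — plus an
Adam optimizer.  Everything is float64 and single-threaded, so identical
seeds give bit-identical training runs.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "einsum",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "silu",
    "elu",
    "clip",
    "reshape",
    "tsum",
    "tmean",
    "dropout",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
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
    """A numpy array with gradient tracking through recorded pullbacks."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # make `ndarray <op> Tensor` defer to the Tensor reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # tuple of (parent Tensor, pullback: out-grad -> parent-grad)
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate ``grad`` (default: ones) to all reachable leaves."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order topological sort
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pull in node._parents:
                pg = pull(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------------
    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other, float))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        data = self.data[key]

        def pull(g, self=self, key=key):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return out

        return _op(data, [(self, pull)])


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data: np.ndarray, parents: Iterable[tuple[Tensor, object]]) -> Tensor:
    out = Tensor(data)
    tracked = tuple((p, pull) for p, pull in parents if p.requires_grad or p._parents)
    out._parents = tracked
    out.requires_grad = bool(tracked)
    return out


# ----------------------------------------------------------------------
# primitive operations
def add(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data + b.data,
        [
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )


def mul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(g * b.data, a.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.shape)),
        ],
    )


def div(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data / b.data,
        [
            (a, lambda g: _unbroadcast(g / b.data, a.shape)),
            (b, lambda g: _unbroadcast(-g * a.data / (b.data**2), b.shape)),
        ],
    )


def power(a, p: float) -> Tensor:
    a = _t(a)
    p = float(p)
    return _op(a.data**p, [(a, lambda g: g * p * a.data ** (p - 1.0))])


def matmul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return _op(
        a.data @ b.data,
        [
            (a, lambda g: g @ b.data.swapaxes(-1, -2)),
            (b, lambda g: a.data.swapaxes(-1, -2) @ g),
        ],
    )


def einsum(subscripts: str, a, b) -> Tensor:
    """Two-operand einsum whose pullback is another einsum.

    Restricted to subscripts without ellipses or repeated letters within
    one operand, and every input letter must appear in the output or in
    the other operand — true for all contractions used in this package.
    """
    a, b = _t(a), _t(b)
    lhs, out_sub = subscripts.replace(" ", "").split("->")
    a_sub, b_sub = lhs.split(",")
    data = np.einsum(subscripts, a.data, b.data)

    def pull_a(g):
        return np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data)

    def pull_b(g):
        return np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data)

    return _op(data, [(a, pull_a), (b, pull_b)])


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _t(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def pull(g):
        if axis is None:
            return np.broadcast_to(g, a.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.shape).copy()

    return _op(data, [(a, pull)])


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _t(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def exp(a) -> Tensor:
    a = _t(a)
    out = np.exp(a.data)
    return _op(out, [(a, lambda g: g * out)])


def log(a) -> Tensor:
    a = _t(a)
    return _op(np.log(a.data), [(a, lambda g: g / a.data)])


def sqrt(a) -> Tensor:
    a = _t(a)
    out = np.sqrt(a.data)
    return _op(out, [(a, lambda g: g * 0.5 / out)])


def sigmoid(a) -> Tensor:
    a = _t(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _op(out, [(a, lambda g: g * out * (1.0 - out))])


def silu(a) -> Tensor:
    """x * sigmoid(x), the base nonlinearity of the KAN layer."""
    a = _t(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s
    return _op(out, [(a, lambda g: g * (s + a.data * s * (1.0 - s)))])


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _t(a)
    neg = np.minimum(a.data, 0.0)
    out = np.where(a.data > 0, a.data, alpha * (np.exp(neg) - 1.0))
    dfdx = np.where(a.data > 0, 1.0, alpha * np.exp(neg))
    return _op(out, [(a, lambda g: g * dfdx)])


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is passed only where the input is interior."""
    a = _t(a)
    out = np.clip(a.data, lo, hi)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(float)
    return _op(out, [(a, lambda g: g * inside)])


def reshape(a, shape) -> Tensor:
    a = _t(a)
    return _op(a.data.reshape(shape), [(a, lambda g: g.reshape(a.shape))])


def concat(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [_t(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    parents = []
    for i, t in enumerate(ts):
        lo, hi = offsets[i], offsets[i + 1]

        def pull(g, lo=lo, hi=hi):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            return g[tuple(index)]

        parents.append((t, pull))
    return _op(data, parents)


def dropout(a, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; only meaningful during training."""
    if p <= 0.0:
        return _t(a)
    mask = (rng.random(_t(a).shape) >= p) / (1.0 - p)
    return mul(a, mask)


# ----------------------------------------------------------------------
class Adam:
    """Adam optimizer over a name->Tensor parameter mapping."""

    def __init__(
        self,
        params: Mapping[str, Tensor] | Iterable[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params.values()) if isinstance(params, Mapping) else list(params)
        if not all(p.requires_grad for p in self.params):
            raise ValueError("all optimized tensors must have requires_grad=True")
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._step = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._step += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self._step
        bc2 = 1.0 - b2**self._step
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
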
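"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the model needs: broadcast arithmetic,
batched matrix products, ReLU/Tanh/logistic nonlinearities, numerically
stable softmax, reductions, reshaping/concatenation, row gathering and
dropout.  Everything is float64 for reproducibility.

Gradients flow only into tensors with ``requires_grad=True`` (or tensors
derived from them); constants never allocate gradient buffers.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "concat",
    "gather_rows",
    "softmax",
    "dropout",
    "backward",
    "Adam",
    "glorot_uniform",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self._parents = parents
        self._backward = backward_fn

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, pow_const(other, -1.0))

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def swap_last(self):
        """Swap the last two axes (matrix transpose of each batch member)."""
        axes = list(range(self.ndim))
        axes[-2], axes[-1] = axes[-1], axes[-2]
        return transpose(self, tuple(axes))


def tensor(data) -> Tensor:
    """Wrap data as a constant (no gradient) tensor."""
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    """Wrap data as a trainable tensor."""
    return Tensor(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    """Add g into t.grad.

    The first contribution aliases g to avoid a copy; a second contribution
    replaces the alias with a fresh sum so shared upstream arrays are never
    mutated in place.
    """
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if g.dtype == np.float64 else g.astype(np.float64)
        t._grad_owned = False
    elif t._grad_owned:
        t.grad += g
    else:
        t.grad = t.grad + g
        t._grad_owned = True


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient g back to `shape` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward_fn) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward_fn=backward_fn if req else None)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), bw)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    # batched input times shared 2-D weight: one flat GEMM instead of a
    # broadcast loop (and, in backward, instead of a giant batched outer
    # product that is summed away immediately)
    if a.ndim > 2 and b.ndim == 2:
        lead = a.shape[:-1]
        out_data = (a.data.reshape(-1, a.shape[-1]) @ b.data).reshape(
            lead + (b.shape[-1],))

        def bw(g):
            g2 = g.reshape(-1, b.shape[-1])
            if a.requires_grad:
                _accumulate(a, (g2 @ b.data.T).reshape(a.shape))
            if b.requires_grad:
                _accumulate(b, a.data.reshape(-1, a.shape[-1]).T @ g2)

        return _make(out_data, (a, b), bw)

    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accumulate(a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accumulate(b, _unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), bw)


def pow_const(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def bw(g):
        _accumulate(a, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def bw(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), bw)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)

    def bw(g):
        _accumulate(a, g * (1.0 - t * t))

    return _make(t, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    s = np.where(a.data >= 0,
                 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500))),
                 np.exp(np.clip(a.data, -500, 500))
                 / (1.0 + np.exp(np.clip(a.data, -500, 500))))

    def bw(g):
        _accumulate(a, g * s * (1.0 - s))

    return _make(s, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` with a fused gradient."""
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _accumulate(a, s * (g - dot))

    return _make(s, (a,), bw)


def reduce_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g_arr = np.asarray(g)
        if axis is not None and not keepdims:
            g_arr = np.expand_dims(g_arr, axis)
        _accumulate(a, np.broadcast_to(g_arr, a.shape).copy())

    return _make(out_data, (a,), bw)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        count = a.data.shape[axis]
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape

    def bw(g):
        _accumulate(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inverse = tuple(np.argsort(axes))

    def bw(g):
        _accumulate(a, g.transpose(inverse))

    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)

    def bw(g):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return _make(out_data, tuple(ts), bw)


def gather_rows(a, indices) -> Tensor:
    """Select rows along axis 0; backward scatter-adds."""
    a = _as_tensor(a)
    idx = np.asarray(indices, dtype=np.intp)

    def bw(g):
        if a.requires_grad:
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
                a._grad_owned = True
            elif not a._grad_owned:
                a.grad = a.grad.copy()
                a._grad_owned = True
            np.add.at(a.grad, idx, g)

    return _make(a.data[idx], (a,), bw)


def dropout(a, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity in evaluation mode or at rate 0."""
    a = _as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.shape) < keep) / keep
    return mul(a, tensor(mask))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def backward(loss: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar loss."""
    if loss.data.size != 1:
        raise ValueError("backward() requires a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
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
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


# ---------------------------------------------------------------------------
# initialisation and optimisation
# ---------------------------------------------------------------------------

def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple | None = None) -> np.ndarray:
    """Variance-scaled uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adaptive-moment gradient descent over a list of parameters."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
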
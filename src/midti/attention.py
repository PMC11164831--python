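"""Deep interactive attention over drug/target layer stacks.

A drug and a target each arrive as a (3·l) × F_m stack of GCN layer
outputs.  One interactive layer applies self-attention (SA) to each side,
then drug-target attention (DTA: drug queries, target keys/values) and
target-drug attention (TDA: the reverse), both consuming the same SA
outputs.  A cascade of such layers concatenates the original inputs plus
every layer's output and projects back to F_m with a linear map; mean
pooling over the stack rows yields the final 1 × F_m representations.

All tensors are batched: (N_pairs, rows, F_m).

An instrumentation hook (:func:`record_attention`) captures every softmax
attention matrix for invariant checks (row-stochasticity).
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

_PROBE: list | None = None


@contextmanager
def record_attention():
    """Collect every attention-weight array computed inside the block."""
    global _PROBE
    prev, _PROBE = _PROBE, []
    try:
        yield _PROBE
    finally:
        _PROBE = prev


@dataclass
class AttentionConfig:
    """Shape/regularisation settings for the interactive attention module."""

    heads: int = 8
    n_layers: int = 3
    f_m: int = 512
    dropout: float = 0.1
    seed: int = 0
    wrap: str = "literal"   # residual/norm placement; see AttentionBlock

    def __post_init__(self):
        if self.f_m % self.heads != 0:
            raise ValueError(
                f"embedding width {self.f_m} not divisible by {self.heads} heads")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.wrap not in ("literal", "standard"):
            raise ValueError("wrap must be 'literal' or 'standard'")


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         d: float | None = None) -> Tensor:
    """softmax(QKᵀ/√d)V; every output row is a convex combination of V
    rows."""
    if d is None:
        d = q.shape[-1]
    scores = (q @ k.swap_last()) * (1.0 / np.sqrt(d))
    att = ad.softmax(scores, axis=-1)
    if _PROBE is not None:
        _PROBE.append(att.data.copy())
    return att @ v


class Linear:
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.w = ad.parameter(ad.glorot_uniform(rng, f_in, f_out))
        self.b = ad.parameter(np.zeros((1, f_out))) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out


class LayerNorm:
    """Normalisation over the last axis with learned affine rescale."""

    def __init__(self, f: int, eps: float = 1e-5):
        self.gamma = ad.parameter(np.ones((1, f)))
        self.beta = ad.parameter(np.zeros((1, f)))
        self.eps = eps
        self.params = [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = ad.pow_const(var + self.eps, -0.5)
        return xc * inv * self.gamma + self.beta


class MultiHeadAttention:
    """Learned Q/K/V projections, per-head scaled-dot attention, head
    concatenation and output projection."""

    def __init__(self, f_m: int, heads: int, rng: np.random.Generator):
        if f_m % heads != 0:
            raise ValueError("f_m must be divisible by heads")
        self.f_m, self.heads = f_m, heads
        self.d_head = f_m // heads
        self.q = Linear(f_m, f_m, rng, bias=False)
        self.k = Linear(f_m, f_m, rng, bias=False)
        self.v = Linear(f_m, f_m, rng, bias=False)
        self.o = Linear(f_m, f_m, rng, bias=False)
        self.params = self.q.params + self.k.params + self.v.params + self.o.params

    def _split(self, x: Tensor, n: int, s: int) -> Tensor:
        return x.reshape((n, s, self.heads, self.d_head)).transpose(0, 2, 1, 3)

    def __call__(self, x_q: Tensor, x_kv: Tensor) -> Tensor:
        squeeze = x_q.ndim == 2
        if squeeze:
            x_q = x_q.reshape((1,) + x_q.shape)
            x_kv = x_kv.reshape((1,) + x_kv.shape)
        n, s_q, _ = x_q.shape
        s_k = x_kv.shape[1]
        q = self._split(self.q(x_q), n, s_q)
        k = self._split(self.k(x_kv), n, s_k)
        v = self._split(self.v(x_kv), n, s_k)
        att = scaled_dot_attention(q, k, v, d=self.d_head)   # (n,h,s_q,d)
        merged = att.transpose(0, 2, 1, 3).reshape((n, s_q, self.f_m))
        out = self.o(merged)
        return out.reshape(out.shape[1:]) if squeeze else out


class FeedForward:
    """Two linear maps with a rectifier between; inner width 4·F_m."""

    def __init__(self, f_m: int, rng: np.random.Generator, inner_mult: int = 4):
        self.l1 = Linear(f_m, inner_mult * f_m, rng)
        self.l2 = Linear(inner_mult * f_m, f_m, rng)
        self.params = self.l1.params + self.l2.params

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(ad.relu(self.l1(x)))


class AttentionBlock:
    """One attention sublayer (self- or cross-) with feed-forward,
    dropout, residual connection and layer normalisation.

    wrap="literal" follows x = LN(x_mha + Dropout(FF(x_mha))): the residual
    and normalisation wrap only the feed-forward path, with the attention
    output as the residual branch.  wrap="standard" is the conventional
    post-norm transformer placement (residual around both sublayers).
    """

    def __init__(self, f_m: int, heads: int, dropout: float,
                 rng: np.random.Generator, wrap: str = "literal"):
        self.mha = MultiHeadAttention(f_m, heads, rng)
        self.ff = FeedForward(f_m, rng)
        self.norm = LayerNorm(f_m)
        self.norm2 = LayerNorm(f_m) if wrap == "standard" else None
        self.dropout = dropout
        self.wrap = wrap
        self.calls = 0
        self.params = self.mha.params + self.ff.params + self.norm.params
        if self.norm2 is not None:
            self.params += self.norm2.params

    def __call__(self, x_q: Tensor, x_kv: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        self.calls += 1
        x_mha = self.mha(x_q, x_kv)
        if self.wrap == "literal":
            ff = ad.dropout(self.ff(x_mha), self.dropout, rng, training)
            return self.norm(x_mha + ff)
        h = self.norm(x_q + ad.dropout(x_mha, self.dropout, rng, training))
        ff = ad.dropout(self.ff(h), self.dropout, rng, training)
        return self.norm2(h + ff)


class InteractiveLayer:
    """SA on each side, then the two cross-attentions sharing those SA
    outputs (2 SA calls per layer)."""

    def __init__(self, f_m: int, heads: int, dropout: float,
                 rng: np.random.Generator, wrap: str = "literal"):
        self.sa_d = AttentionBlock(f_m, heads, dropout, rng, wrap)
        self.sa_t = AttentionBlock(f_m, heads, dropout, rng, wrap)
        self.dta = AttentionBlock(f_m, heads, dropout, rng, wrap)
        self.tda = AttentionBlock(f_m, heads, dropout, rng, wrap)
        self.params = (self.sa_d.params + self.sa_t.params
                       + self.dta.params + self.tda.params)

    def __call__(self, x_d: Tensor, x_t: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None):
        s_d = self.sa_d(x_d, x_d, training, rng)
        s_t = self.sa_t(x_t, x_t, training, rng)
        out_d = self.dta(s_d, s_t, training, rng)
        out_t = self.tda(s_t, s_d, training, rng)
        return out_d, out_t


class InteractiveAttention:
    """Cascade of interactive layers with skip-concatenation.

    The outputs of layers 0..n (layer 0 being the raw inputs) are
    concatenated along the feature axis and projected back to F_m by W_r
    (drugs) and W_s (targets), each of shape ((n+1)·F_m) × F_m.
    """

    def __init__(self, config: AttentionConfig,
                 rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        self.layers = [
            InteractiveLayer(config.f_m, config.heads, config.dropout, rng,
                             config.wrap)
            for _ in range(config.n_layers)
        ]
        width = (config.n_layers + 1) * config.f_m
        self.w_r = ad.parameter(ad.glorot_uniform(rng, width, config.f_m))
        self.w_s = ad.parameter(ad.glorot_uniform(rng, width, config.f_m))
        self.params = [self.w_r, self.w_s]
        for layer in self.layers:
            self.params += layer.params

    def __call__(self, x_d: Tensor, x_t: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None):
        outs_d, outs_t = [x_d], [x_t]
        cur_d, cur_t = x_d, x_t
        for layer in self.layers:
            cur_d, cur_t = layer(cur_d, cur_t, training, rng)
            outs_d.append(cur_d)
            outs_t.append(cur_t)
        cat_d = outs_d[0] if len(outs_d) == 1 else ad.concat(outs_d, axis=-1)
        cat_t = outs_t[0] if len(outs_t) == 1 else ad.concat(outs_t, axis=-1)
        return cat_d @ self.w_r, cat_t @ self.w_s


def pool(x: Tensor | np.ndarray) -> Tensor:
    """Mean over the stack rows: (N, rows, F) → (N, F) or (rows, F) → (1, F)."""
    t = x if isinstance(x, Tensor) else ad.tensor(x)
    if t.ndim == 2:
        return t.mean(axis=0, keepdims=True)
    return t.mean(axis=1)


# functional aliases matching the operation vocabulary
def sa_block(block: AttentionBlock, x: Tensor, **kw) -> Tensor:
    return block(x, x, **kw)


def dta_block(block: AttentionBlock, x_d: Tensor, x_t: Tensor, **kw) -> Tensor:
    return block(x_d, x_t, **kw)


def tda_block(block: AttentionBlock, x_t: Tensor, x_d: Tensor, **kw) -> Tensor:
    return block(x_t, x_d, **kw)
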
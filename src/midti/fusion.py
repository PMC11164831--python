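"""Unsupervised multi-view similarity network fusion.

Each similarity view is encoded by a one-layer graph convolution over
one-hot node features; a per-node view-attention softmax combines the
per-view embeddings into one feature matrix X; a dot-product decoder with a
logistic squash reconstructs a network from X; training minimises the mean
squared reconstruction error against every original view.  The repaired
reconstruction is the integrated similarity network A_homo and X the node
feature matrix handed to the downstream encoders.

All per-view encoders share one initial weight draw: the views are
exchangeable a priori, so symmetric initialisation (they differentiate only
through their gradients) avoids arbitrary asymmetry between identical
views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .data_io import SimilarityMatrix, repair_similarity
from .gcn import normalize_adjacency
from .simnet import ViewSet

logger = logging.getLogger("midti.fusion")


class FusionError(RuntimeError):
    """Fusion training failed (e.g. NaN loss)."""


@dataclass
class FusionConfig:
    """Settings for the fusion stage.

    dim is the embedding width F0 (defaults to the downstream width F_m so
    X feeds the first supervised GCN layer directly); va toggles the
    view-attention combiner (off = unweighted mean over views).
    """

    dim: int = 512
    epochs: int = 500
    lr: float = 0.01
    seed: int = 0
    va: bool = True


@dataclass
class FusedNetwork:
    """Output of fusion: integrated network, node features, view weights."""

    a_homo: SimilarityMatrix
    x: np.ndarray                 # n × F0
    view_weights: np.ndarray      # n × V, rows sum to 1
    loss_history: list = field(default_factory=list)


def encode_view(a_view: np.ndarray | SimilarityMatrix, weight: Tensor,
                activation=ad.tanh) -> Tensor:
    """One graph-convolution layer over one-hot features.

    With one-hot inputs the propagation D̃^{-1/2}(A+I)D̃^{-1/2} · I · W
    collapses to A_norm @ W.  The nonlinearity is tanh: the dot-product
    decoder σ(XXᵀ) can only reach values below 0.5 when embedding dot
    products can be negative, so the encoder output must be sign-symmetric.
    """
    a = a_view.values if isinstance(a_view, SimilarityMatrix) else np.asarray(a_view)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("view adjacency must be square")
    a_norm = normalize_adjacency(a)
    out = ad.tensor(a_norm) @ weight
    return activation(out) if activation is not None else out


def view_attention(embeddings: list[Tensor], score: Tensor,
                   va: bool = True) -> tuple[Tensor, Tensor]:
    """Combine per-view embeddings with a per-node softmax over views.

    Each view's logit for node i is the dot product of its embedding row
    with a learned scoring vector.  With va=False the combiner is the
    unweighted mean (the "w/o VA" ablation arm).
    """
    if not embeddings:
        raise ValueError("view_attention needs at least one view")
    n = embeddings[0].shape[0]
    v = len(embeddings)
    if va:
        logits = ad.concat([emb @ score for emb in embeddings], axis=1)  # n × V
        weights = ad.softmax(logits, axis=1)
    else:
        weights = ad.tensor(np.full((n, v), 1.0 / v))
    parts = []
    for j, emb in enumerate(embeddings):
        w_col = ad.gather_rows(weights.swap_last(), [j]).swap_last()  # n × 1
        parts.append(emb * w_col)
    fused = parts[0]
    for p in parts[1:]:
        fused = fused + p
    return fused, weights


def reconstruct(x: Tensor) -> Tensor:
    """Dot-product decoder with a logistic squash: Â = σ(X Xᵀ) ∈ (0,1),
    symmetric by construction."""
    return ad.sigmoid(x @ x.swap_last())


def fusion_loss(a_hat: Tensor, views: ViewSet | list[np.ndarray]) -> Tensor:
    """Mean over views of the mean squared error between Â and each view."""
    arrays = views.arrays() if isinstance(views, ViewSet) else list(views)
    total = None
    for a in arrays:
        diff = a_hat - ad.tensor(a)
        term = (diff * diff).mean()
        total = term if total is None else total + term
    return total * (1.0 / len(arrays))


def fuse_networks(views: ViewSet, config: FusionConfig) -> FusedNetwork:
    """Train encoders + view attention + decoder end-to-end and return the
    integrated network, node features and per-node view weights."""
    n = views.node_count
    rng = np.random.default_rng(config.seed)
    w_init = ad.glorot_uniform(rng, n, config.dim)
    enc_weights = [ad.parameter(w_init.copy()) for _ in views.views]
    score = ad.parameter(ad.glorot_uniform(rng, config.dim, 1))
    params = enc_weights + [score]

    a_norms = [normalize_adjacency(v.values) for v in views.views]
    a_norm_tensors = [ad.tensor(a) for a in a_norms]

    def forward():
        embs = [ad.tanh(a_t @ w) for a_t, w in zip(a_norm_tensors, enc_weights)]
        fused, weights = view_attention(embs, score, va=config.va)
        a_hat = reconstruct(fused)
        return fused, weights, a_hat

    opt = ad.Adam(params, lr=config.lr)
    history: list[float] = []
    for epoch in range(config.epochs):
        _, _, a_hat = forward()
        loss = fusion_loss(a_hat, views)
        val = float(loss.data)
        if not np.isfinite(val):
            raise FusionError(
                f"fusion loss became non-finite at epoch {epoch} "
                f"(lr={config.lr}, dim={config.dim}); history tail: "
                f"{history[-5:]}")
        history.append(val)
        opt.zero_grad()
        ad.backward(loss)
        opt.step()

    fused, weights, a_hat = forward()
    a_homo = repair_similarity(a_hat.data, name="a_homo")
    return FusedNetwork(
        a_homo=SimilarityMatrix(a_homo, view_name="integrated"),
        x=fused.data.copy(),
        view_weights=weights.data.copy(),
        loss_history=history,
    )


def fuse_baseline(views: ViewSet, strategy: str,
                  literal_pro: bool = False) -> SimilarityMatrix:
    """Closed-form fusion baselines.

    "ave" is the entrywise arithmetic mean of the views.  "pro" combines
    the views as a noisy-OR, 1 − Π(1 − S_v); the literal product form
    1 − Π S_v is available behind literal_pro for comparison, although it
    is degenerate when all views agree at 1.
    """
    arrays = views.arrays()
    if strategy == "ave":
        fused = np.mean(arrays, axis=0)
    elif strategy == "pro":
        if literal_pro:
            prod = np.ones_like(arrays[0])
            for a in arrays:
                prod = prod * a
            fused = 1.0 - prod
        else:
            prod = np.ones_like(arrays[0])
            for a in arrays:
                prod = prod * (1.0 - a)
            fused = 1.0 - prod
    else:
        raise ValueError(f"unknown fusion strategy {strategy!r}")
    fused = repair_similarity(fused, name=f"fused_{strategy}")
    return SimilarityMatrix(fused, view_name=f"fused_{strategy}")
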
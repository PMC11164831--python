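"""Graph-convolutional embedding of drugs and targets from three networks.

The three network types are the integrated homogeneous similarity networks
(one for drugs, one for targets), the drug-target bipartite network built
from training-fold interactions only, and the heterogeneous network that
places both homogeneous blocks on the diagonal and the bipartite block off
the diagonal.  Each network is propagated with the renormalised rule
X ← σ(D̃^{-1/2}(A+I)D̃^{-1/2} X W), every intermediate layer is kept, and a
node's embeddings from all enabled networks and layers are stacked into a
(3·l) × F_m matrix (fewer rows when networks are ablated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

NETWORK_ORDER = ("homo", "bi", "hete")


class LeakageError(AssertionError):
    """A held-out interaction is present in a training network."""


@dataclass
class HeteroNetwork:
    """(n_d+n_t)² block adjacency; drugs occupy indices 0..n_d-1."""

    a: np.ndarray
    n_drugs: int
    n_targets: int

    def __post_init__(self):
        n = self.n_drugs + self.n_targets
        if self.a.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}, got {self.a.shape}")
        if np.abs(self.a - self.a.T).max() > 1e-9:
            raise ValueError("heterogeneous adjacency must be symmetric")

    @property
    def bipartite_block(self) -> np.ndarray:
        return self.a[: self.n_drugs, self.n_drugs:]


@dataclass
class LayerStack:
    """Per-node stack of GCN layer outputs: one row per (network, layer)."""

    rows: np.ndarray              # (k·l) × F_m
    ordering: tuple               # e.g. ("homo", "bi", "hete")
    layers_per_network: int

    def __post_init__(self):
        expected = len(self.ordering) * self.layers_per_network
        if self.rows.shape[0] != expected:
            raise ValueError(
                f"stack must have {expected} rows, got {self.rows.shape[0]}")
        if not np.isfinite(self.rows).all():
            raise ValueError("stack contains non-finite entries")


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Renormalised adjacency D̃^{-1/2}(A+I)D̃^{-1/2} with D̃ the degree
    matrix of A+I."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_forward(a_norm, x0, weights, activation=ad.relu) -> list[Tensor]:
    """Apply l graph-convolution layers, returning every layer's output."""
    a_t = a_norm if isinstance(a_norm, Tensor) else ad.tensor(a_norm)
    h = x0 if isinstance(x0, Tensor) else ad.tensor(x0)
    outputs: list[Tensor] = []
    for w in weights:
        h = a_t @ h @ w
        if activation is not None:
            h = activation(h)
        outputs.append(h)
    return outputs


def build_bipartite(dti_train: np.ndarray) -> HeteroNetwork:
    """Bipartite DTI adjacency: zero homogeneous blocks, training
    interactions off-diagonal."""
    b = np.asarray(dti_train, dtype=np.float64)
    n_d, n_t = b.shape
    a = np.zeros((n_d + n_t, n_d + n_t))
    a[:n_d, n_d:] = b
    a[n_d:, :n_d] = b.T
    return HeteroNetwork(a=a, n_drugs=n_d, n_targets=n_t)


def build_hetero(a_homo_d: np.ndarray, a_homo_t: np.ndarray,
                 dti_train: np.ndarray) -> HeteroNetwork:
    """Heterogeneous adjacency: homogeneous blocks on the diagonal plus the
    bipartite block."""
    b = np.asarray(dti_train, dtype=np.float64)
    n_d, n_t = b.shape
    if a_homo_d.shape != (n_d, n_d) or a_homo_t.shape != (n_t, n_t):
        raise ValueError("homogeneous block shapes inconsistent with DTI matrix")
    a = np.zeros((n_d + n_t, n_d + n_t))
    a[:n_d, :n_d] = a_homo_d
    a[n_d:, n_d:] = a_homo_t
    a[:n_d, n_d:] = b
    a[n_d:, :n_d] = b.T
    return HeteroNetwork(a=a, n_drugs=n_d, n_targets=n_t)


def assert_no_leakage(network: HeteroNetwork | np.ndarray,
                      test_pairs: np.ndarray,
                      n_drugs: int | None = None) -> None:
    """Exhaustively verify no held-out interaction appears as an edge."""
    if isinstance(network, HeteroNetwork):
        block = network.bipartite_block
    else:
        block = np.asarray(network)[:n_drugs, n_drugs:]
    for d, t in np.asarray(test_pairs):
        if block[d, t] != 0:
            raise LeakageError(
                f"held-out interaction ({d},{t}) present in training network")


def stack_embeddings(homo_layers, bi_layers, hete_layers, node: int,
                     enabled=(True, True, True)) -> LayerStack:
    """Stack one node's per-layer embeddings from the enabled networks, in
    the documented homo → bi → hete order."""
    groups = []
    ordering = []
    for name, layers, on in zip(NETWORK_ORDER,
                                (homo_layers, bi_layers, hete_layers), enabled):
        if not on:
            continue
        for h in layers:
            arr = h.data if isinstance(h, Tensor) else np.asarray(h)
            groups.append(arr[node])
        ordering.append(name)
    depths = {len(layers) for layers, on in
              zip((homo_layers, bi_layers, hete_layers), enabled) if on}
    if len(depths) != 1:
        raise ValueError("all enabled networks must have the same depth")
    l = depths.pop()
    return LayerStack(rows=np.vstack(groups), ordering=tuple(ordering),
                      layers_per_network=l)


class MultiNetworkEncoder:
    """Trainable GCN encoders over the enabled networks, producing batched
    per-node layer stacks for drugs and targets.

    Initial features: the homogeneous networks start from the fusion
    feature matrices X_d / X_t; the bipartite and heterogeneous networks
    start from the vertical stack [X_d; X_t], each side first projected to
    the embedding width when the two feature widths differ.
    """

    def __init__(self, a_homo_d: np.ndarray, a_homo_t: np.ndarray,
                 x_d: np.ndarray, x_t: np.ndarray, dti_train: np.ndarray,
                 n_layers: int = 3, embed_dim: int = 512,
                 use_homo: bool = True, use_bi: bool = True,
                 use_hete: bool = True,
                 rng: np.random.Generator | None = None):
        if not (use_homo or use_bi or use_hete):
            raise ValueError(
                "at least one of use_homo/use_bi/use_hete must be enabled")
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.n_drugs, self.n_targets = dti_train.shape
        self.n_layers = n_layers
        self.embed_dim = embed_dim
        self.use = {"homo": use_homo, "bi": use_bi, "hete": use_hete}

        self._a_homo_d = ad.tensor(normalize_adjacency(a_homo_d))
        self._a_homo_t = ad.tensor(normalize_adjacency(a_homo_t))
        self._a_bi = ad.tensor(normalize_adjacency(build_bipartite(dti_train).a))
        self._a_hete = ad.tensor(normalize_adjacency(
            build_hetero(a_homo_d, a_homo_t, dti_train).a))

        f_d, f_t = x_d.shape[1], x_t.shape[1]
        self._x_d = ad.tensor(x_d)
        self._x_t = ad.tensor(x_t)
        self.params: list[Tensor] = []

        self._proj_d = self._proj_t = None
        if f_d != f_t:
            self._proj_d = ad.parameter(ad.glorot_uniform(rng, f_d, embed_dim))
            self._proj_t = ad.parameter(ad.glorot_uniform(rng, f_t, embed_dim))
            self.params += [self._proj_d, self._proj_t]
            f_joint = embed_dim
        else:
            f_joint = f_d

        def make_weights(f_in):
            ws = []
            for i in range(n_layers):
                fi = f_in if i == 0 else embed_dim
                ws.append(ad.parameter(ad.glorot_uniform(rng, fi, embed_dim)))
            return ws

        self._w = {}
        if use_homo:
            self._w["homo_d"] = make_weights(f_d)
            self._w["homo_t"] = make_weights(f_t)
        if use_bi:
            self._w["bi"] = make_weights(f_joint)
        if use_hete:
            self._w["hete"] = make_weights(f_joint)
        for ws in self._w.values():
            self.params += ws

    @property
    def networks_enabled(self) -> int:
        return sum(self.use.values())

    @property
    def stack_rows(self) -> int:
        return self.networks_enabled * self.n_layers

    def _joint_features(self) -> Tensor:
        if self._proj_d is not None:
            xd = self._x_d @ self._proj_d
            xt = self._x_t @ self._proj_t
        else:
            xd, xt = self._x_d, self._x_t
        return ad.concat([xd, xt], axis=0)

    def forward(self) -> tuple[Tensor, Tensor]:
        """Return (drug_stacks, target_stacks) of shape (n, k·l, F_m)."""
        n_d = self.n_drugs
        drug_groups: list[Tensor] = []
        target_groups: list[Tensor] = []

        if self.use["homo"]:
            for h in gcn_forward(self._a_homo_d, self._x_d, self._w["homo_d"]):
                drug_groups.append(h)
            for h in gcn_forward(self._a_homo_t, self._x_t, self._w["homo_t"]):
                target_groups.append(h)
        joint = None
        for name in ("bi", "hete"):
            if not self.use[name]:
                continue
            if joint is None:
                joint = self._joint_features()
            a_norm = self._a_bi if name == "bi" else self._a_hete
            for h in gcn_forward(a_norm, joint, self._w[name]):
                drug_groups.append(ad.gather_rows(h, np.arange(n_d)))
                target_groups.append(ad.gather_rows(
                    h, np.arange(n_d, n_d + self.n_targets)))

        def as_stack(groups: list[Tensor], n: int) -> Tensor:
            expanded = [g.reshape((n, 1, self.embed_dim)) for g in groups]
            return ad.concat(expanded, axis=1)

        return (as_stack(drug_groups, n_d),
                as_stack(target_groups, self.n_targets))
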
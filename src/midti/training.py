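"""End-to-end model assembly, cross-validated training and ablations.

The pipeline: similarity views → unsupervised fusion (frozen afterwards) →
per-fold masked networks → GCN stacks → interactive attention → MLP scorer,
trained jointly against binary cross-entropy with an adaptive-moment
optimiser.  For every evaluation fold the held-out interactions are removed
from the bipartite and heterogeneous adjacencies before training, and an
exhaustive leakage assertion verifies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .attention import AttentionConfig, InteractiveAttention, pool
from .config import RunConfig
from .data_io import (AssociationMatrix, InteractionDataset, build_dataset,
                      load_matrix, save_checkpoint)
from .fusion import FusedNetwork, FusionConfig, fuse_baseline, fuse_networks
from .gcn import MultiNetworkEncoder, assert_no_leakage, build_bipartite
from .predictor import (MetricsReport, MLPPredictor, bce_loss,
                        compute_metrics, pair_embed)
from .simnet import ViewSet, build_drug_views, build_target_views
from .synthetic import LUO_FILE_NAMES, SyntheticData

logger = logging.getLogger("midti.training")


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the last finite parameter state."""

    def __init__(self, msg: str, last_good_state: dict | None = None):
        super().__init__(msg)
        self.last_good_state = last_good_state


@dataclass
class ProblemData:
    """Similarity views plus the interaction matrix for one dataset."""

    drug_views: ViewSet
    target_views: ViewSet
    dti: AssociationMatrix


def load_problem(directory) -> ProblemData:
    """Read a dataset directory in the dense-text dialect and build the
    five drug / four target views."""
    d = Path(directory)

    def assoc(key, row_kind, col_kind):
        return load_matrix(d / LUO_FILE_NAMES[key], "association",
                           row_kind=row_kind, col_kind=col_kind)

    dti = assoc("dti", "drug", "target")
    drug_views = build_drug_views(
        assoc("drug_drug", "drug", "drug"),
        assoc("drug_disease", "drug", "disease"),
        assoc("drug_sideeffect", "drug", "side-effect"),
        dti,
        load_matrix(d / LUO_FILE_NAMES["chem_sim"], "similarity",
                    name="chemical"),
    )
    target_views = build_target_views(
        assoc("protein_protein", "target", "target"),
        assoc("protein_disease", "target", "disease"),
        dti,
        load_matrix(d / LUO_FILE_NAMES["seq_sim"], "similarity",
                    name="sequence"),
    )
    return ProblemData(drug_views=drug_views, target_views=target_views,
                       dti=dti)


def problem_from_synthetic(data: SyntheticData) -> ProblemData:
    drug_views, target_views = data.views()
    return ProblemData(drug_views=drug_views, target_views=target_views,
                       dti=data.dti)


def fuse_problem(problem: ProblemData,
                 config: RunConfig) -> tuple[FusedNetwork, FusedNetwork]:
    """Run the configured fusion strategy on both sides.

    The attention strategy trains the graph-autoencoder fusion; the ave/pro
    baselines are closed-form, with the integrated similarity rows doubling
    as node features.
    """
    if config.fusion_strategy == "attention":
        fcfg_d = FusionConfig(dim=config.fusion_dim, epochs=config.fusion_epochs,
                              lr=config.fusion_lr, seed=config.seed,
                              va=config.va)
        fcfg_t = FusionConfig(dim=config.fusion_dim, epochs=config.fusion_epochs,
                              lr=config.fusion_lr, seed=config.seed + 1,
                              va=config.va)
        return (fuse_networks(problem.drug_views, fcfg_d),
                fuse_networks(problem.target_views, fcfg_t))

    def baseline(views: ViewSet) -> FusedNetwork:
        fused = fuse_baseline(views, config.fusion_strategy,
                              literal_pro=config.literal_pro)
        n, v = views.node_count, len(views)
        return FusedNetwork(a_homo=fused, x=fused.values.copy(),
                            view_weights=np.full((n, v), 1.0 / v))

    return baseline(problem.drug_views), baseline(problem.target_views)


class MIDTIModel:
    """GCN stacks + interactive attention + MLP scorer over frozen fusion
    outputs."""

    def __init__(self, fused_d: FusedNetwork, fused_t: FusedNetwork,
                 dti_train: np.ndarray, config: RunConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = MultiNetworkEncoder(
            fused_d.a_homo.values, fused_t.a_homo.values,
            fused_d.x, fused_t.x, dti_train,
            n_layers=config.gcn_layers, embed_dim=config.embed_dim,
            use_homo=config.use_homo, use_bi=config.use_bi,
            use_hete=config.use_hete, rng=rng)
        self.ia = None
        if config.ia:
            acfg = AttentionConfig(heads=config.heads,
                                   n_layers=config.ia_layers,
                                   f_m=config.embed_dim,
                                   dropout=config.dropout,
                                   seed=seed, wrap=config.attn_wrap)
            self.ia = InteractiveAttention(acfg, rng)
        self.mlp = MLPPredictor(2 * config.embed_dim, config.mlp_layers, rng,
                                literal_tanh=config.literal_tanh)
        self.params = list(self.encoder.params) + self.mlp.params
        if self.ia is not None:
            self.params += self.ia.params

    def forward(self, pairs: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Score (drug, target) index pairs; returns (ŷ, pair embeddings f)."""
        d_stacks, t_stacks = self.encoder.forward()
        x_d = ad.gather_rows(d_stacks, pairs[:, 0])
        x_t = ad.gather_rows(t_stacks, pairs[:, 1])
        if self.ia is not None:
            x_d, x_t = self.ia(x_d, x_t, training=training, rng=rng)
        f = pair_embed(pool(x_d), pool(x_t))
        return self.mlp(f), f

    def scores(self, pairs: np.ndarray) -> np.ndarray:
        y_hat, _ = self.forward(pairs, training=False)
        return y_hat.data.ravel()

    def pair_embeddings(self, pairs: np.ndarray) -> np.ndarray:
        _, f = self.forward(pairs, training=False)
        return f.data.copy()

    def state_dict(self) -> dict:
        return {f"param_{i}": p.data.copy() for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params):
            p.data[...] = state[f"param_{i}"]


def masked_dti(dataset: InteractionDataset, fold: int,
               mask: bool = True) -> np.ndarray:
    """Interaction matrix containing training-fold positives only."""
    mat = np.zeros((dataset.n_drugs, dataset.n_targets))
    pos = dataset.pairs[dataset.labels == 1]
    pos_folds = dataset.folds[dataset.labels == 1]
    keep = pos if not mask else pos[pos_folds != fold]
    mat[keep[:, 0], keep[:, 1]] = 1.0
    return mat


def train_fold(dataset: InteractionDataset, fold: int,
               fused_d: FusedNetwork, fused_t: FusedNetwork,
               config: RunConfig):
    """Train on four folds, evaluate on the held-out fold.

    Returns (model, metrics_row, loss_history).  Fully reproducible for a
    given config and seed; aborts with the last finite parameter state if
    the loss diverges.
    """
    train_idx, test_idx = dataset.fold_indices(fold)
    dti_train = masked_dti(dataset, fold, mask=config.mask_test_edges)

    test_pos = dataset.pairs[test_idx][dataset.labels[test_idx] == 1]
    if config.mask_test_edges:
        assert_no_leakage(build_bipartite(dti_train), test_pos)

    seed = (config.seed * 131 + fold * 7 + 1) % (2 ** 31)
    model = MIDTIModel(fused_d, fused_t, dti_train, config, seed)
    drop_rng = np.random.default_rng(seed + 1)

    pairs_train = dataset.pairs[train_idx]
    y_train = dataset.labels[train_idx]

    opt = ad.Adam(model.params, lr=config.lr)
    history: list[float] = []
    best = np.inf
    best_state: dict | None = None
    stall = 0
    for epoch in range(config.epochs):
        y_hat, _ = model.forward(pairs_train, training=True, rng=drop_rng)
        loss = bce_loss(y_hat, y_train)
        val = float(loss.data)
        if not np.isfinite(val):
            raise TrainingDivergedError(
                f"training loss non-finite at epoch {epoch} "
                f"(lr={opt.lr}); last finite losses: {history[-5:]}",
                last_good_state=best_state)
        history.append(val)
        if val < best - 1e-6:
            best, stall = val, 0
            best_state = model.state_dict()
        else:
            stall += 1
            if config.lr_decay and stall >= config.patience and opt.lr > 1e-4:
                opt.lr *= 0.1
                stall = 0
                logger.info("fold %d: plateau at epoch %d, lr -> %g",
                            fold, epoch, opt.lr)
        opt.zero_grad()
        ad.backward(loss)
        opt.step()

    scores = model.scores(dataset.pairs[test_idx])
    row = compute_metrics(scores, dataset.labels[test_idx],
                          threshold=config.threshold)
    return model, row, history


def run_experiment(problem: ProblemData, config: RunConfig,
                   dataset: InteractionDataset | None = None,
                   fused: tuple[FusedNetwork, FusedNetwork] | None = None,
                   folds=None, checkpoint_dir=None) -> MetricsReport:
    """Full protocol: fuse once, then 5-fold CV; reports per-fold metrics
    and their arithmetic mean.  With checkpoint_dir set, each fold's
    trained parameters are saved as fold<k>.ckpt."""
    if dataset is None:
        dataset = build_dataset(problem.dti, ratio=config.ratio,
                                seed=config.seed)
    if fused is None:
        fused = fuse_problem(problem, config)
    fused_d, fused_t = fused
    report = MetricsReport()
    for fold in (range(config.n_folds) if folds is None else folds):
        model, row, _ = train_fold(dataset, fold, fused_d, fused_t, config)
        report.add(row)
        logger.info("fold %d: %s", fold,
                    {k: round(v, 4) for k, v in row.items()})
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model.state_dict(), path / f"fold{fold}.ckpt")
    return report


VA_IA_ARMS = ((False, False), (True, False), (False, True), (True, True))
NETWORK_ARMS = ((True, False, False), (False, True, False),
                (False, False, True), (True, True, False),
                (True, False, True), (False, True, True),
                (True, True, True))
FUSION_ARMS = ("ave", "pro", "attention")


def run_ablation(problem: ProblemData, config: RunConfig, grid: str,
                 folds=None) -> pd.DataFrame:
    """Ablation table over one of the three grids.

    grid="va_ia" toggles the view-attention and interactive-attention
    mechanisms (4 arms); grid="networks" enables each non-empty subset of
    {homo, bi, hete} (7 arms); grid="fusion" compares the ave/pro baselines
    with the attention fusion (3 arms).  Arms share the dataset, the seed
    and every other config key, so differences are attributable to the
    toggle alone.
    """
    dataset = build_dataset(problem.dti, ratio=config.ratio, seed=config.seed)
    rows = []
    if grid == "va_ia":
        arms = [{"va": va, "ia": ia} for va, ia in VA_IA_ARMS]
    elif grid == "networks":
        arms = [{"use_homo": h, "use_bi": b, "use_hete": e}
                for h, b, e in NETWORK_ARMS]
    elif grid == "fusion":
        arms = [{"fusion_strategy": s} for s in FUSION_ARMS]
    else:
        raise ValueError(f"unknown ablation grid {grid!r}")
    for arm in arms:
        arm_config = config.replace(**arm)
        report = run_experiment(problem, arm_config, dataset=dataset,
                                folds=folds)
        row = dict(arm)
        row.update(report.mean)
        row["config_hash"] = arm_config.config_hash
        rows.append(row)
    return pd.DataFrame(rows)
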
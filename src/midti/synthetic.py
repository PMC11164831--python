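"""Synthetic multi-view DTI benchmark with planted community structure.

Drugs and targets are partitioned into balanced communities.  Every
association view assigns each column (disease, side effect, neighbour, ...)
to a community and draws Bernoulli edges at a high within-community rate
against a low background rate, so interaction profiles carry the community
signal the way real association data does.  Interactions are drawn from a
community-level affinity matrix and then label-flipped with a small noise
probability.  The "chemical" and "sequence" similarity surrogates are
Jaccard similarities of independent held-out association draws: only the
matrix contract matters to the method, not real chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .data_io import AssociationMatrix, SimilarityMatrix, save_matrix
from .simnet import ViewSet, build_drug_views, build_target_views, jaccard_similarity

logger = logging.getLogger("midti.synthetic")

# within-community association rate; the SyntheticSpec density is the
# cross-community background rate
P_IN = 0.5


@dataclass
class SyntheticSpec:
    """Generator settings: sizes, community structure, affinity, noise."""

    n_drugs: int = 50
    n_targets: int = 80
    k_d: int = 3
    k_t: int = 4
    affinity: np.ndarray | None = None      # k_d × k_t in [0,1]
    assoc_density: float = 0.05
    noise: float = 0.01
    n_diseases: int = 60
    n_side_effects: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.affinity is None:
            # each drug community binds one target community strongly
            aff = np.full((self.k_d, self.k_t), 0.02)
            for i in range(self.k_d):
                aff[i, i % self.k_t] = 0.9
            self.affinity = aff
        self.affinity = np.asarray(self.affinity, dtype=np.float64)
        if self.affinity.shape != (self.k_d, self.k_t):
            raise ValueError("affinity must be k_d × k_t")
        if self.affinity.min() < 0 or self.affinity.max() > 1:
            raise ValueError("affinity entries must lie in [0,1]")
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must lie in [0, 0.5)")


@dataclass
class SyntheticData:
    """Everything the pipeline consumes, plus the planted ground truth."""

    drug_drug: AssociationMatrix
    drug_disease: AssociationMatrix
    drug_sideeffect: AssociationMatrix
    protein_protein: AssociationMatrix
    protein_disease: AssociationMatrix
    chem_sim: SimilarityMatrix
    seq_sim: SimilarityMatrix
    dti: AssociationMatrix
    drug_communities: np.ndarray
    target_communities: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)

    def views(self) -> tuple[ViewSet, ViewSet]:
        """Build the five drug / four target similarity views."""
        drug = build_drug_views(self.drug_drug, self.drug_disease,
                                self.drug_sideeffect, self.dti, self.chem_sim)
        target = build_target_views(self.protein_protein, self.protein_disease,
                                    self.dti, self.seq_sim)
        return drug, target


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


def _community_assoc(rng: np.random.Generator, labels: np.ndarray,
                     n_cols: int, k: int, background: float,
                     row_kind: str, col_kind: str) -> AssociationMatrix:
    """Bernoulli association block whose columns belong to communities."""
    col_labels = _balanced_labels(n_cols, k, rng)
    prob = np.where(labels[:, None] == col_labels[None, :], P_IN, background)
    values = (rng.random((len(labels), n_cols)) < prob).astype(float)
    return AssociationMatrix(values, row_kind=row_kind, col_kind=col_kind)


def _community_square(rng: np.random.Generator, labels: np.ndarray,
                      background: float, kind: str) -> AssociationMatrix:
    """Symmetric binary interaction network with community blocks."""
    n = len(labels)
    prob = np.where(labels[:, None] == labels[None, :], P_IN, background)
    upper = rng.random((n, n)) < prob
    values = np.triu(upper, 1)
    values = (values | values.T).astype(float)
    return AssociationMatrix(values, row_kind=kind, col_kind=kind)


def generate(spec: SyntheticSpec, max_attempts: int = 10) -> SyntheticData:
    """Draw one dataset; regenerates (with diagnostics) if the affinity
    draw yields no positive interactions."""
    for attempt in range(max_attempts):
        rng = np.random.default_rng(spec.seed + 99991 * attempt)
        c_d = _balanced_labels(spec.n_drugs, spec.k_d, rng)
        c_t = _balanced_labels(spec.n_targets, spec.k_t, rng)

        prob = spec.affinity[c_d[:, None], c_t[None, :]]
        dti_vals = (rng.random((spec.n_drugs, spec.n_targets)) < prob)
        if spec.noise > 0:
            flips = rng.random(dti_vals.shape) < spec.noise
            dti_vals = dti_vals ^ flips
        dti_vals = dti_vals.astype(float)
        if dti_vals.sum() == 0:
            logger.warning(
                "attempt %d: affinity draw produced zero interactions "
                "(mean affinity %.4f); regenerating", attempt,
                float(spec.affinity.mean()))
            continue

        bg = spec.assoc_density
        data = SyntheticData(
            drug_drug=_community_square(rng, c_d, bg, "drug"),
            drug_disease=_community_assoc(rng, c_d, spec.n_diseases, spec.k_d,
                                          bg, "drug", "disease"),
            drug_sideeffect=_community_assoc(rng, c_d, spec.n_side_effects,
                                             spec.k_d, bg, "drug",
                                             "side-effect"),
            protein_protein=_community_square(rng, c_t, bg, "target"),
            protein_disease=_community_assoc(rng, c_t, spec.n_diseases,
                                             spec.k_t, bg, "target",
                                             "disease"),
            chem_sim=SimilarityMatrix(
                jaccard_similarity(_community_assoc(
                    rng, c_d, 50, spec.k_d, bg, "drug", "disease").values).values,
                view_name="chemical"),
            seq_sim=SimilarityMatrix(
                jaccard_similarity(_community_assoc(
                    rng, c_t, 50, spec.k_t, bg, "target", "disease").values).values,
                view_name="sequence"),
            dti=AssociationMatrix(dti_vals, row_kind="drug", col_kind="target"),
            drug_communities=c_d,
            target_communities=c_t,
            spec=spec,
        )
        return data
    raise RuntimeError(
        f"no positive interactions after {max_attempts} attempts; "
        f"affinity matrix too sparse: {spec.affinity}")


def expected_dti_density(spec: SyntheticSpec) -> float:
    """Closed-form expected interaction rate, including noise flips, for
    balanced community sizes."""
    sizes_d = np.bincount(np.arange(spec.n_drugs) % spec.k_d,
                          minlength=spec.k_d).astype(float)
    sizes_t = np.bincount(np.arange(spec.n_targets) % spec.k_t,
                          minlength=spec.k_t).astype(float)
    block = sizes_d[:, None] * sizes_t[None, :]
    p = spec.affinity * (1 - spec.noise) + (1 - spec.affinity) * spec.noise
    return float((block * p).sum() / block.sum())


def easy_fixture(seed: int = 0) -> tuple[SyntheticData, RunConfig]:
    """A small, strongly structured instance plus a reduced-width run
    configuration, sized so the full pipeline trains in minutes on one CPU.
    """
    spec = SyntheticSpec(n_drugs=50, n_targets=80, k_d=3, k_t=4,
                         assoc_density=0.05, noise=0.01, seed=seed)
    data = generate(spec)
    config = RunConfig(embed_dim=32, heads=4, gcn_layers=2, ia_layers=2,
                       mlp_layers=3, dropout=0.1, lr=0.01, epochs=200,
                       lr_decay=False, fusion_dim=32, fusion_epochs=200,
                       fusion_lr=0.01, ratio=1, seed=seed)
    return data, config


LUO_FILE_NAMES = {
    "dti": "mat_drug_protein.txt",
    "drug_drug": "mat_drug_drug.txt",
    "drug_disease": "mat_drug_disease.txt",
    "drug_sideeffect": "mat_drug_se.txt",
    "protein_protein": "mat_protein_protein.txt",
    "protein_disease": "mat_protein_disease.txt",
    "chem_sim": "Similarity_Matrix_Drugs.txt",
    "seq_sim": "Similarity_Matrix_Proteins.txt",
}


def write_dataset(data: SyntheticData, directory) -> None:
    """Write the generated dataset in the dense-text dialect the loader
    reads, closing the generate → save → load loop."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_matrix(data.dti.values, d / LUO_FILE_NAMES["dti"])
    save_matrix(data.drug_drug.values, d / LUO_FILE_NAMES["drug_drug"])
    save_matrix(data.drug_disease.values, d / LUO_FILE_NAMES["drug_disease"])
    save_matrix(data.drug_sideeffect.values, d / LUO_FILE_NAMES["drug_sideeffect"])
    save_matrix(data.protein_protein.values, d / LUO_FILE_NAMES["protein_protein"])
    save_matrix(data.protein_disease.values, d / LUO_FILE_NAMES["protein_disease"])
    save_matrix(data.chem_sim.values, d / LUO_FILE_NAMES["chem_sim"])
    save_matrix(data.seq_sim.values, d / LUO_FILE_NAMES["seq_sim"])
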
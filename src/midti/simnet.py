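"""Similarity-view construction from association profiles.

Each binary association matrix (rows = the entities being compared) is
turned into a similarity network via the Jaccard index of row supports:
S[i,j] = |P_i ∩ P_j| / |P_i ∪ P_j|.  A drug is described by five views
(drug-drug interactions, drug-disease, drug-side-effect, drug-protein
associations, chemical structure); a target by four (protein-protein,
protein-disease, protein-drug associations, sequence similarity).  The
chemical and sequence views arrive as precomputed similarity matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, SimilarityMatrix

DRUG_VIEW_ORDER = ("drug_drug", "drug_disease", "drug_sideeffect",
                   "drug_protein", "chemical")
TARGET_VIEW_ORDER = ("protein_protein", "protein_disease",
                     "protein_drug", "sequence")


class ViewSetError(ValueError):
    """Inconsistent node counts or duplicate view names."""


@dataclass
class ViewSet:
    """Ordered collection of same-sized similarity views over one node set."""

    views: list[SimilarityMatrix]
    node_count: int = field(default=0)

    def __post_init__(self):
        if not self.views:
            raise ViewSetError("a ViewSet needs at least one view")
        n = self.views[0].n
        for v in self.views:
            if v.n != n:
                raise ViewSetError(
                    f"view {v.view_name!r} has {v.n} nodes, expected {n}")
        names = [v.view_name for v in self.views]
        if len(set(names)) != len(names):
            raise ViewSetError(f"duplicate view names: {names}")
        self.node_count = n

    def __len__(self) -> int:
        return len(self.views)

    @property
    def names(self) -> list[str]:
        return [v.view_name for v in self.views]

    def arrays(self) -> list[np.ndarray]:
        return [v.values for v in self.views]


def jaccard_similarity(assoc: AssociationMatrix | np.ndarray,
                       view_name: str = "jaccard") -> SimilarityMatrix:
    """Jaccard index over binary row profiles.

    The diagonal is always 1 (an entity is identical to itself even with an
    empty profile), and two distinct entities with empty profiles get 0,
    which keeps the 0/0 case out of the division.
    """
    m = assoc.values if isinstance(assoc, AssociationMatrix) else np.asarray(assoc)
    m = m.astype(np.float64)
    inter = m @ m.T
    support = m.sum(axis=1)
    union = support[:, None] + support[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, view_name=view_name)


def _check_rows(name: str, mat: AssociationMatrix, n: int) -> None:
    if mat.values.shape[0] != n:
        raise ViewSetError(
            f"{name}: expected {n} rows, got {mat.values.shape[0]}")


def build_drug_views(drug_drug: AssociationMatrix,
                     drug_disease: AssociationMatrix,
                     drug_sideeffect: AssociationMatrix,
                     drug_protein: AssociationMatrix,
                     chem_sim: SimilarityMatrix) -> ViewSet:
    """The five drug views, in the documented order: interaction profile,
    disease profile, side-effect profile, target profile, chemical
    structure."""
    n = drug_drug.values.shape[0]
    if drug_drug.values.shape != (n, n):
        raise ViewSetError("drug_drug must be square")
    for name, mat in (("drug_disease", drug_disease),
                      ("drug_sideeffect", drug_sideeffect),
                      ("drug_protein", drug_protein)):
        _check_rows(name, mat, n)
    if chem_sim.n != n:
        raise ViewSetError(f"chem_sim: expected {n} nodes, got {chem_sim.n}")
    views = [
        jaccard_similarity(drug_drug, "drug_drug"),
        jaccard_similarity(drug_disease, "drug_disease"),
        jaccard_similarity(drug_sideeffect, "drug_sideeffect"),
        jaccard_similarity(drug_protein, "drug_protein"),
        SimilarityMatrix(chem_sim.values, view_name="chemical"),
    ]
    return ViewSet(views)


def build_target_views(protein_protein: AssociationMatrix,
                       protein_disease: AssociationMatrix,
                       drug_protein: AssociationMatrix,
                       seq_sim: SimilarityMatrix) -> ViewSet:
    """The four target views: interaction profile, disease profile, drug
    profile (transpose of the drug-protein associations), sequence."""
    n = protein_protein.values.shape[0]
    if protein_protein.values.shape != (n, n):
        raise ViewSetError("protein_protein must be square")
    _check_rows("protein_disease", protein_disease, n)
    if drug_protein.values.shape[1] != n:
        raise ViewSetError(
            f"drug_protein: expected {n} columns, got "
            f"{drug_protein.values.shape[1]}")
    if seq_sim.n != n:
        raise ViewSetError(f"seq_sim: expected {n} nodes, got {seq_sim.n}")
    views = [
        jaccard_similarity(protein_protein, "protein_protein"),
        jaccard_similarity(protein_disease, "protein_disease"),
        jaccard_similarity(drug_protein.values.T, "protein_drug"),
        SimilarityMatrix(seq_sim.values, view_name="sequence"),
    ]
    return ViewSet(views)
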
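"""Reading, writing and validating on-disk artifacts.

The matrix file dialect is dense whitespace-delimited numeric text with no
header (the format the DTINet-lineage datasets ship in).  Row order defines
entity identity; all indices are 0-based.  Similarity matrices are repaired
on load (symmetrised, clipped to [0,1], unit diagonal) and every repair is
logged, never silent.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("midti.data_io")

SYM_TOL = 1e-8


class MatrixParseError(ValueError):
    """Malformed matrix text (ragged rows, non-numeric fields)."""


class MatrixValidationError(ValueError):
    """Parsed matrix violates its declared contract."""


class CheckpointError(IOError):
    """Checkpoint file missing, truncated or corrupted."""


@dataclass
class AssociationMatrix:
    """Binary entity-by-entity relation profile.

    ``row_kind``/``col_kind`` record the entity roles (drug, target,
    disease, side-effect); the values themselves are strictly 0/1.
    """

    values: np.ndarray
    row_kind: str = "drug"
    col_kind: str = "target"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        validate_association(self.values)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0,1] with unit diagonal."""

    values: np.ndarray
    view_name: str = "similarity"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        validate_similarity(self.values, self.view_name)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class InteractionDataset:
    """Positive/negative drug-target pairs with 5-fold assignments.

    ``pairs`` stacks positives then negatives; ``labels`` holds 1/0 and
    ``folds`` the fold id (0..4) of each sample.  Positives and negatives
    are folded independently so every fold preserves the global ratio.
    """

    pairs: np.ndarray          # (N, 2) int array of (drug, target)
    labels: np.ndarray         # (N,) 0/1
    folds: np.ndarray          # (N,) in 0..4
    ratio: int
    seed: int
    n_drugs: int = 0
    n_targets: int = 0

    @property
    def positives(self) -> np.ndarray:
        return self.pairs[self.labels == 1]

    @property
    def negatives(self) -> np.ndarray:
        return self.pairs[self.labels == 0]

    def fold_indices(self, fold: int):
        """Return (train_idx, test_idx) sample index arrays for a fold."""
        test = np.flatnonzero(self.folds == fold)
        train = np.flatnonzero(self.folds != fold)
        return train, test


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def validate_association(values: np.ndarray) -> None:
    if values.ndim != 2 or min(values.shape) == 0:
        raise MatrixValidationError("association matrix must be 2-D and non-empty")
    if np.isnan(values).any():
        raise MatrixValidationError("association matrix contains NaN")
    bad = (values != 0) & (values != 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixValidationError(
            f"association matrix entry ({i},{j})={values[i, j]!r} is not 0/1")


def validate_similarity(values: np.ndarray, name: str = "similarity") -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixValidationError(f"{name}: similarity matrix must be square")
    if np.isnan(values).any():
        raise MatrixValidationError(f"{name}: similarity matrix contains NaN")
    if np.abs(values - values.T).max() > SYM_TOL:
        raise MatrixValidationError(f"{name}: matrix not symmetric within {SYM_TOL}")
    if values.min() < -SYM_TOL or values.max() > 1 + SYM_TOL:
        raise MatrixValidationError(f"{name}: entries outside [0,1]")
    if np.abs(np.diag(values) - 1.0).max() > SYM_TOL:
        raise MatrixValidationError(f"{name}: diagonal must be 1")


def repair_similarity(values: np.ndarray, name: str = "similarity") -> np.ndarray:
    """Symmetrise as (M+Mᵀ)/2, clip to [0,1], force unit diagonal.

    Each repair actually applied is logged at WARNING level.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixValidationError(f"{name}: similarity matrix must be square")
    if np.isnan(values).any():
        raise MatrixValidationError(f"{name}: similarity matrix contains NaN")
    out = values
    if np.abs(out - out.T).max() > SYM_TOL:
        logger.warning("%s: symmetrized as (M + M.T)/2", name)
        out = (out + out.T) / 2.0
    if out.min() < 0 or out.max() > 1:
        logger.warning("%s: clipped entries to [0,1]", name)
        out = np.clip(out, 0.0, 1.0)
    if np.abs(np.diag(out) - 1.0).max() > SYM_TOL:
        logger.warning("%s: forced unit diagonal", name)
        out = out.copy()
        np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# matrix text files
# ---------------------------------------------------------------------------

def _parse_dense_text(path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                row = [float(x) for x in fields]
            except ValueError as exc:
                raise MatrixParseError(
                    f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise MatrixParseError(
                    f"{path}:{lineno}: ragged row (got {len(row)} fields, "
                    f"expected {width})")
            rows.append(row)
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=np.float64)


def load_matrix(path, kind: str, name: str | None = None,
                row_kind: str = "drug", col_kind: str = "target"):
    """Load a dense whitespace-delimited matrix file.

    kind="association" returns an :class:`AssociationMatrix` (entries must
    be 0/1); kind="similarity" returns a :class:`SimilarityMatrix` after
    repair (symmetrisation, clipping, unit diagonal — all logged).
    """
    values = _parse_dense_text(path)
    label = name or Path(path).stem
    if kind == "association":
        return AssociationMatrix(values, row_kind=row_kind, col_kind=col_kind)
    if kind == "similarity":
        return SimilarityMatrix(repair_similarity(values, label), view_name=label)
    raise ValueError(f"unknown matrix kind {kind!r}")


def save_matrix(values: np.ndarray, path) -> None:
    """Write a matrix in the dense text dialect (load ∘ save is identity
    up to 1e-6)."""
    np.savetxt(path, np.asarray(values, dtype=np.float64), fmt="%.10g")


def dataset_summary(directory) -> dict:
    """Contract check of a DTINet-dialect dataset directory.

    Expects mat_drug_protein.txt, mat_drug_drug.txt, mat_drug_disease.txt,
    mat_drug_se.txt, mat_protein_protein.txt, mat_protein_disease.txt.
    Returns entity counts, the number of known interactions, and the total
    node count of the heterogeneous graph
    (drugs + targets + diseases + side-effects).
    """
    d = Path(directory)
    dti = load_matrix(d / "mat_drug_protein.txt", "association")
    dd = load_matrix(d / "mat_drug_drug.txt", "association",
                     row_kind="drug", col_kind="drug")
    ddis = load_matrix(d / "mat_drug_disease.txt", "association",
                       row_kind="drug", col_kind="disease")
    dse = load_matrix(d / "mat_drug_se.txt", "association",
                      row_kind="drug", col_kind="side-effect")
    pp = load_matrix(d / "mat_protein_protein.txt", "association",
                     row_kind="target", col_kind="target")
    pdis = load_matrix(d / "mat_protein_disease.txt", "association",
                       row_kind="target", col_kind="disease")
    n_drugs, n_targets = dti.shape
    checks = {
        "drug_drug": dd.shape,
        "drug_disease": ddis.shape,
        "drug_se": dse.shape,
        "protein_protein": pp.shape,
        "protein_disease": pdis.shape,
    }
    if dd.shape != (n_drugs, n_drugs) or pp.shape != (n_targets, n_targets):
        raise MatrixValidationError(
            f"inconsistent entity counts across files: {checks}")
    if ddis.shape[0] != n_drugs or dse.shape[0] != n_drugs \
            or pdis.shape[0] != n_targets:
        raise MatrixValidationError(
            f"inconsistent entity counts across files: {checks}")
    if ddis.shape[1] != pdis.shape[1]:
        raise MatrixValidationError("drug and protein disease columns differ")
    return {
        "n_drugs": int(n_drugs),
        "n_targets": int(n_targets),
        "n_diseases": int(ddis.shape[1]),
        "n_side_effects": int(dse.shape[1]),
        "n_interactions": int(dti.values.sum()),
        "n_nodes": int(n_drugs + n_targets + ddis.shape[1] + dse.shape[1]),
    }


# ---------------------------------------------------------------------------
# interaction dataset with ratio-controlled negatives and 5-fold labels
# ---------------------------------------------------------------------------

def _stratified_folds(n: int, rng: np.random.Generator,
                      n_folds: int = 5) -> np.ndarray:
    """Balanced fold labels: counts differ by at most 1."""
    labels = np.arange(n) % n_folds
    rng.shuffle(labels)
    return labels


def build_dataset(dti: AssociationMatrix, ratio: int, seed: int,
                  n_folds: int = 5) -> InteractionDataset:
    """All 1-cells as positives; `ratio` negatives per positive sampled
    uniformly without replacement from the 0-cells; stratified folds."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    values = dti.values
    positives = np.argwhere(values == 1)
    if len(positives) == 0:
        raise MatrixValidationError("interaction matrix has no positives")
    zeros = np.argwhere(values == 0)
    n_wanted = ratio * len(positives)
    rng = np.random.default_rng(seed)
    if n_wanted > len(zeros):
        logger.warning(
            "requested %d negatives but only %d non-edges exist; using all",
            n_wanted, len(zeros))
        negatives = zeros
    else:
        pick = rng.choice(len(zeros), size=n_wanted, replace=False)
        negatives = zeros[pick]
    folds_pos = _stratified_folds(len(positives), rng, n_folds)
    folds_neg = _stratified_folds(len(negatives), rng, n_folds)
    pairs = np.vstack([positives, negatives]).astype(np.intp)
    labels = np.concatenate([np.ones(len(positives), dtype=np.intp),
                             np.zeros(len(negatives), dtype=np.intp)])
    folds = np.concatenate([folds_pos, folds_neg])
    return InteractionDataset(pairs=pairs, labels=labels, folds=folds,
                              ratio=ratio, seed=seed,
                              n_drugs=values.shape[0],
                              n_targets=values.shape[1])


def load_edge_list(path) -> tuple[np.ndarray, np.ndarray]:
    """TSV edge list (drug_id, target_id, label) → (pairs, labels)."""
    pairs, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            pairs.append((int(fields[0]), int(fields[1])))
            labels.append(int(fields[2]))
    return np.asarray(pairs, dtype=np.intp), np.asarray(labels, dtype=np.intp)


# ---------------------------------------------------------------------------
# reports and checkpoints
# ---------------------------------------------------------------------------

def save_report(metrics: dict, path) -> None:
    """Write a metrics report as sorted-key JSON (byte-stable for a given
    metrics dict)."""
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


_CKPT_MAGIC = b"MIDTICKPT1"


def save_checkpoint(state: dict, path) -> None:
    """Serialize a {name: array} parameter state with a CRC trailer."""
    payload = {}
    for k, v in state.items():
        arr = np.asarray(v, dtype=np.float64)
        payload[k] = {"shape": list(arr.shape), "data": arr.ravel().tolist()}
    body = json.dumps(payload, sort_keys=True).encode()
    crc = zlib.crc32(body).to_bytes(4, "big")
    with open(path, "wb") as fh:
        fh.write(_CKPT_MAGIC + crc + body)


def load_checkpoint(path) -> dict:
    try:
        with open(path, "rb") as fh:
            blob = fh.read()
    except OSError as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if len(blob) < len(_CKPT_MAGIC) + 4 or not blob.startswith(_CKPT_MAGIC):
        raise CheckpointError(f"{path}: not a checkpoint file")
    crc = int.from_bytes(blob[len(_CKPT_MAGIC):len(_CKPT_MAGIC) + 4], "big")
    body = blob[len(_CKPT_MAGIC) + 4:]
    if zlib.crc32(body) != crc:
        raise CheckpointError(f"{path}: checkpoint corrupted (CRC mismatch)")
    payload = json.loads(body)
    return {k: np.asarray(v["data"], dtype=np.float64).reshape(v["shape"])
            for k, v in payload.items()}
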
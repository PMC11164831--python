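"""2-D projection of learned pair embeddings for external plotting.

Writes a TSV (x, y, label) rather than figures; the projection is t-SNE by
default with a PCA option for tiny or deterministic-critical runs.
"""

from __future__ import annotations

import numpy as np


def project_embeddings(embeddings: np.ndarray, method: str = "tsne",
                       seed: int = 0) -> np.ndarray:
    """Project (N, d) pair embeddings to (N, 2)."""
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[0] < 2:
        raise ValueError("need at least two embeddings to project")
    if method == "pca":
        from sklearn.decomposition import PCA
        return PCA(n_components=2, random_state=seed).fit_transform(emb)
    if method == "tsne":
        from sklearn.manifold import TSNE
        perplexity = min(30.0, max(2.0, (emb.shape[0] - 1) / 3.0))
        return TSNE(n_components=2, random_state=seed,
                    perplexity=perplexity, init="pca").fit_transform(emb)
    raise ValueError(f"unknown projection method {method!r}")


def write_projection_tsv(coords: np.ndarray, labels, path) -> None:
    labels = np.asarray(labels).ravel()
    if coords.shape[0] != labels.shape[0]:
        raise ValueError("coords and labels must align")
    with open(path, "w") as fh:
        fh.write("x\ty\tlabel\n")
        for (x, y), lab in zip(coords, labels):
            fh.write(f"{x:.6f}\t{y:.6f}\t{int(lab)}\n")
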
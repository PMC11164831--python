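"""Pair scoring and evaluation metrics.

The final drug and target vectors are concatenated (drug first) and scored
by a small MLP.  Hidden layers use Tanh; the final scalar passes through a
logistic squash so the score lies in (0,1) and the cross-entropy objective
is well defined.  A literal-tanh mode instead rescales (tanh+1)/2 for the
variant that keeps Tanh as the output activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, matthews_corrcoef, roc_auc_score)

from . import _autodiff as ad
from ._autodiff import Tensor

METRIC_KEYS = ("ACC", "AUC", "AUPR", "F1", "MCC")


def pair_embed(x_d: Tensor, x_t: Tensor) -> Tensor:
    """f = x̂_d ∥ x̂_t, drug first; width 2·F_m."""
    if x_d.shape != x_t.shape:
        raise ValueError(
            f"drug/target vectors must match: {x_d.shape} vs {x_t.shape}")
    return ad.concat([x_d, x_t], axis=-1)


class MLPPredictor:
    """MLP decoder: (n_layers−1) Tanh hidden layers with halving widths,
    then a linear output squashed into (0,1)."""

    def __init__(self, f_in: int, n_layers: int, rng: np.random.Generator,
                 literal_tanh: bool = False):
        if n_layers < 1:
            raise ValueError("MLP needs at least one layer")
        from .attention import Linear
        self.literal_tanh = literal_tanh
        self.layers = []
        d = f_in
        for _ in range(n_layers - 1):
            d_out = max(d // 2, 8)
            self.layers.append(Linear(d, d_out, rng))
            d = d_out
        self.out = Linear(d, 1, rng)
        self.params = [p for l in self.layers for p in l.params] + self.out.params

    def __call__(self, f: Tensor) -> Tensor:
        h = f
        for layer in self.layers:
            h = ad.tanh(layer(h))
        z = self.out(h)
        if not np.isfinite(z.data).all():
            raise FloatingPointError("predictor produced non-finite logits")
        if self.literal_tanh:
            return (ad.tanh(z) + 1.0) * 0.5
        return ad.sigmoid(z)


def predict(mlp: MLPPredictor, f: Tensor) -> Tensor:
    """Score a batch of pair embeddings; returns probabilities in (0,1)."""
    return mlp(f)


def bce_loss(y_hat: Tensor, y, eps: float = 1e-12) -> Tensor:
    """Mean binary cross-entropy −(1/N)Σ y·log ŷ + (1−y)·log(1−ŷ).

    Scores are nudged into [eps, 1−eps] inside the graph so saturated
    probabilities cannot produce infinities.
    """
    y_arr = np.asarray(y, dtype=np.float64).reshape(-1, 1)
    if y_hat.ndim == 1:
        y_hat = y_hat.reshape((-1, 1))
    p = y_hat * (1.0 - 2.0 * eps) + eps
    yt = ad.tensor(y_arr)
    ll = yt * ad.log(p) + (1.0 - yt) * ad.log(1.0 - p)
    return -ll.mean()


@dataclass
class MetricsReport:
    """Per-fold metric rows and their arithmetic mean."""

    per_fold: list = field(default_factory=list)

    def add(self, row: dict) -> None:
        self.per_fold.append({k: float(row[k]) for k in METRIC_KEYS})

    @property
    def mean(self) -> dict:
        return {k: float(np.mean([row[k] for row in self.per_fold]))
                for k in METRIC_KEYS}

    def to_dict(self) -> dict:
        d = dict(self.mean)
        d["per_fold"] = self.per_fold
        return d


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """ACC/F1/MCC at the threshold, AUC and AUPR from the score ranking.

    Ties in the ranking count one half (trapezoidal ROC); AUPR is the
    step-interpolated precision-recall area.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = (scores >= threshold).astype(int)
    row = {
        "ACC": float(accuracy_score(labels, pred)),
        "F1": float(f1_score(labels, pred, zero_division=0)),
        "MCC": float(matthews_corrcoef(labels, pred)),
    }
    if labels.min() == labels.max():
        row["AUC"] = float("nan")
        row["AUPR"] = float("nan")
    else:
        row["AUC"] = float(roc_auc_score(labels, scores))
        row["AUPR"] = float(average_precision_score(labels, scores))
    return row
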
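"""Reference-based cell-type label transfer via logistic regression.

One L2-regularised logistic classifier is trained per reference cell type
(one-vs-rest) on standardized log-normalised expression of a shared
feature set.  Query cells are scored by every classifier after applying
the *reference* standardization (no re-fitting on the query), and scores
are averaged within query clusters: the cluster x reference-type matrix of
mean predicted probabilities measures the similarity between query
clusters and the reference cell types.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ReferenceModel",
    "train_reference",
    "predict_scores",
    "aggregate_cluster_scores",
]


@dataclass
class ReferenceModel:
    """Per-type logistic models plus the reference standardization stats."""

    features: list[str]
    classes: list[str]
    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray  # (n_classes,)
    mean: np.ndarray  # (n_features,) reference per-gene means
    sd: np.ndarray  # (n_features,) reference per-gene SDs (0 -> 1)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "classes": self.classes,
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept.tolist(),
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["features"],
            d["classes"],
            np.asarray(d["coef"]),
            np.asarray(d["intercept"]),
            np.asarray(d["mean"]),
            np.asarray(d["sd"]),
        )


def _select_hvg(X: np.ndarray, genes: pd.Index, n_features: int) -> np.ndarray:
    """Indices of the most variable reference genes (dispersion = variance)."""
    var = X.var(axis=1)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[: min(n_features, len(genes))])


def train_reference(
    expr: pd.DataFrame,
    labels,
    penalty_strength: float = 1.0,
    n_features: int = 2000,
    min_cells: int = 10,
    seed: int = 0,
) -> ReferenceModel:
    """Fit one-vs-rest L2 logistic classifiers on reference expression.

    ``expr`` is genes x cells (log-normalised); ``penalty_strength`` is the
    inverse-regularisation C of scikit-learn (smaller = stronger penalty).
    Types with fewer than ``min_cells`` cells are dropped with a warning.
    Features are the ``n_features`` most variable reference genes,
    standardized with reference means/SDs.
    """
    labels = pd.Series(np.asarray(labels))
    X = expr.to_numpy(dtype=float)
    keep_types = []
    for t, cnt in labels.value_counts().items():
        if cnt >= min_cells:
            keep_types.append(t)
        else:
            warnings.warn(f"type {t!r} has {cnt} < {min_cells} cells; dropped", stacklevel=2)
    keep_types = sorted(keep_types)
    if len(keep_types) < 2:
        raise ValueError("need >= 2 reference types with enough cells")
    cell_mask = labels.isin(keep_types).to_numpy()
    X = X[:, cell_mask]
    y = labels[cell_mask].to_numpy()

    feat_idx = _select_hvg(X, expr.index, n_features)
    Xf = X[feat_idx].T  # cells x features
    mu = Xf.mean(axis=0)
    sd = Xf.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (Xf - mu) / sd

    coef = np.empty((len(keep_types), Z.shape[1]))
    intercept = np.empty(len(keep_types))
    for i, t in enumerate(keep_types):
        clf = LogisticRegression(  # default penalty is L2
            C=penalty_strength, solver="lbfgs", max_iter=2000, random_state=seed
        )
        clf.fit(Z, (y == t).astype(int))
        coef[i] = clf.coef_[0]
        intercept[i] = clf.intercept_[0]
    return ReferenceModel(
        features=list(expr.index[feat_idx]),
        classes=list(keep_types),
        coef=coef,
        intercept=intercept,
        mean=mu,
        sd=sd,
    )


def predict_scores(
    expr: pd.DataFrame,
    model: ReferenceModel,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Sigmoid probability per (query cell, reference type).

    Query genes are matched to the model's feature list; features missing
    from the query are imputed at the reference-standardized zero (i.e. the
    reference mean).  Errors out when fewer than ``min_overlap`` of the
    model features are present.
    """
    present = [g for g in model.features if g in expr.index]
    coverage = len(present) / len(model.features)
    if coverage < min_overlap:
        raise ValueError(
            f"query covers {coverage:.1%} of model features, below the "
            f"required {min_overlap:.0%}"
        )
    n_cells = expr.shape[1]
    Z = np.zeros((n_cells, len(model.features)))
    pos = {g: j for j, g in enumerate(model.features)}
    rows = [pos[g] for g in present]
    Q = expr.loc[present].to_numpy(dtype=float).T  # cells x present features
    Z[:, rows] = (Q - model.mean[rows]) / model.sd[rows]
    logits = Z @ model.coef.T + model.intercept
    probs = 1.0 / (1.0 + np.exp(-logits))
    return pd.DataFrame(probs, index=expr.columns, columns=model.classes)


def aggregate_cluster_scores(scores: pd.DataFrame, cluster_labels) -> pd.DataFrame:
    """Arithmetic mean of per-cell scores within each query cluster."""
    clusters = pd.Series(np.asarray(cluster_labels), index=scores.index)
    if clusters.isna().any():
        raise ValueError("every cell must carry a cluster label")
    return scores.groupby(clusters).mean().sort_index()
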
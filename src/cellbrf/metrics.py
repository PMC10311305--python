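"""Evaluation statistics: k-NN consistency and Balance Entropy.

k-NN consistency is the fraction of each cell's k nearest Euclidean
neighbors (self excluded) that share its type, averaged over cells:

    F'_k = sum_i sum_{j in kNN(i)} F(i, j) / (c k)

with F(i, j) = 1 when cells i and j have the same type.

Balance Entropy measures class-size imbalance: with Shannon entropy
H = -sum_i (T_i/c) ln(T_i/c) of the class-size distribution,

    BE = 1 - H / ln(n)

is 0 for perfectly balanced classes and approaches 1 under extreme
imbalance. BE is invariant to the logarithm base (the ratio cancels);
H itself is reported in nats. ARI, NMI and silhouette are standard
measures delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

__all__ = [
    "ClassDistribution",
    "knn_consistency",
    "shannon_entropy",
    "balance_entropy",
    "evaluation_report",
    "adjusted_rand_score",
    "normalized_mutual_info_score",
    "silhouette_score",
]


@dataclass
class ClassDistribution:
    """Positive class sizes T_1..T_n with total c."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 1 or self.sizes.size == 0:
            raise ValueError("sizes must be a non-empty 1-D vector")
        if (self.sizes <= 0).any():
            raise ValueError("all class sizes must be positive")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "ClassDistribution":
        _, counts = np.unique(np.asarray(labels), return_counts=True)
        return cls(sizes=counts)

    @property
    def n(self) -> int:
        return self.sizes.size

    @property
    def c(self) -> float:
        return float(self.sizes.sum())


def knn_consistency(coords: np.ndarray, types: np.ndarray, k: int) -> float:
    """Average fraction of same-type cells among each cell's k nearest
    Euclidean neighbors (self excluded; distance ties break by index)."""
    coords = np.asarray(coords, dtype=float)
    types = np.asarray(types)
    c = coords.shape[0]
    if types.shape[0] != c:
        raise ValueError("types do not align with coordinates")
    if not 1 <= k < c:
        raise ValueError(f"need 1 <= k < c, got k={k}, c={c}")
    sq = np.einsum("ij,ij->i", coords, coords)
    d2 = sq[:, None] - 2.0 * coords @ coords.T + sq[None, :]
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    same = types[order] == types[:, None]
    return float(same.sum() / (c * k))


def shannon_entropy(d: ClassDistribution) -> float:
    """Shannon entropy H = -sum (T_i/c) ln(T_i/c), in nats."""
    p = d.sizes / d.c
    return float(-(p * np.log(p)).sum())


def balance_entropy(d: ClassDistribution) -> float:
    """Balance Entropy BE = 1 - H/ln(n); 0 = balanced, -> 1 = extreme.

    A single class is perfectly 'balanced' by convention: BE = 0.
    """
    if d.n == 1:
        return 0.0
    return float(1.0 - shannon_entropy(d) / np.log(d.n))


def evaluation_report(
    coords: np.ndarray,
    types: np.ndarray,
    predicted: np.ndarray | None = None,
    ks: tuple[int, ...] = (1, 3, 5, 10, 15),
) -> pd.DataFrame:
    """One-row summary: BE, k-NN consistency per k, ARI/NMI/silhouette.

    ``coords`` is the cells x features matrix of the feature space under
    evaluation, ``types`` the reference cell types; ``predicted`` (if
    given) is a clustering to score against ``types``.
    """
    types = np.asarray(types)
    row: dict[str, float] = {
        "balance_entropy": balance_entropy(ClassDistribution.from_labels(types)),
    }
    c = coords.shape[0]
    for k in ks:
        if k < c:
            row[f"knn_consistency_k{k}"] = knn_consistency(coords, types, k)
    if len(np.unique(types)) > 1:
        row["silhouette"] = float(silhouette_score(coords, types))
    if predicted is not None:
        row["ari"] = float(adjusted_rand_score(types, predicted))
        row["nmi"] = float(normalized_mutual_info_score(types, predicted))
    return pd.DataFrame([row])
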
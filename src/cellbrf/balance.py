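"""Cluster-size balancing: oversample rare clusters, undersample major ones.

The reference size is the *central* cluster — the predicted cluster whose
size is closest to ``h = c / n``. Clusters smaller than the central one
are *rare* and are grown to the central size by SMOTE-style interpolation
between within-cluster nearest neighbors; clusters larger than it are
*major* and are shrunk by keeping the fraction ``U`` (default 80%) of
cells closest to the cluster centroid.

Balancing operates in the log-normalized gene space. Synthetic cells are
convex combinations ``i + u (j - i)``, ``u ~ Uniform(0, 1)``, of a seed
cell ``i`` and one of its ``smote_k`` nearest same-cluster neighbors
``j``, so every synthetic cell lies componentwise inside the segment
between its two parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterLabeling
from .data import ExpressionMatrix

__all__ = [
    "BalancePlan",
    "BalancedDataset",
    "plan_balance",
    "smote_oversample",
    "center_undersample",
    "balance",
]

BALANCE_MODES = ("both", "over_only", "under_only", "none")


@dataclass
class BalancePlan:
    """Roles and sampling rates for each predicted cluster."""

    central_cluster: int
    role_of: dict[int, str]  # cluster id -> "central" | "rare" | "major"
    sampling_rate: dict[int, float]  # rare cluster id -> T_central / T_rare
    retain_fraction: float = 0.8
    smote_k: int = 5

    @property
    def rare_clusters(self) -> list[int]:
        return sorted(c for c, r in self.role_of.items() if r == "rare")

    @property
    def major_clusters(self) -> list[int]:
        return sorted(c for c, r in self.role_of.items() if r == "major")


@dataclass
class BalancedDataset:
    """Post-balancing matrix (genes x cells), labels and provenance."""

    values: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray  # "original" | "synthetic" per cell

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if not (self.values.shape[1] == self.labels.size == self.provenance.size):
            raise ValueError("values, labels and provenance disagree on cell count")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=int(self.labels.max()) + 1)


def plan_balance(
    lab: ClusterLabeling, U: float = 0.8, smote_k: int = 5
) -> BalancePlan:
    """Classify clusters as central / rare / major relative to h = c/n.

    The central cluster minimizes |T_C - h|; ties break toward the
    smaller cluster, then the lower cluster id. Rare clusters get a
    sampling rate R = T_central / T_rare (> 1).
    """
    if not 0 < U <= 1:
        raise ValueError("retain fraction U must be in (0, 1]")
    sizes = lab.sizes
    h = lab.h
    central = min(range(lab.n), key=lambda cl: (abs(sizes[cl] - h), sizes[cl], cl))
    t_central = int(sizes[central])
    role_of: dict[int, str] = {}
    rate: dict[int, float] = {}
    for cl in range(lab.n):
        t = int(sizes[cl])
        if cl == central:
            role_of[cl] = "central"
        elif t < t_central:
            role_of[cl] = "rare"
            rate[cl] = t_central / t
        elif t > t_central:
            role_of[cl] = "major"
        else:
            # same size as central: nothing to resample
            role_of[cl] = "central"
    # exactly one cluster is *the* central; equal-size peers keep the
    # central role label but only `central` is the reference
    return BalancePlan(
        central_cluster=central,
        role_of=role_of,
        sampling_rate=rate,
        retain_fraction=U,
        smote_k=smote_k,
    )


def _within_cluster_knn(data: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per column of a genes x cells block.

    Stable ordering: ties at equal distance break by cell index.
    """
    pts = data.T  # cells x genes
    t = pts.shape[0]
    sq = np.einsum("ij,ij->i", pts, pts)
    d2 = sq[:, None] - 2.0 * pts @ pts.T + sq[None, :]
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def smote_oversample(
    data: np.ndarray,
    n_synthetic: int,
    smote_k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize ``n_synthetic`` cells within one rare cluster.

    ``data`` is the genes x T_rare block of the cluster's cells. The
    t-th synthetic cell takes seed cell ``i = t mod T_rare`` (cycling
    through the cluster in column order), draws ``j`` uniformly from
    i's ``smote_k`` nearest within-cluster neighbors and a scalar
    ``u ~ Uniform(0,1)``, and emits ``i + u (j - i)``.

    A single-cell cluster cannot be interpolated: the cell is duplicated
    with a warning.
    """
    g, t_rare = data.shape
    if n_synthetic <= 0:
        return np.empty((g, 0))
    if t_rare == 1:
        warnings.warn(
            "rare cluster has a single cell; duplicating it instead of "
            "interpolating",
            stacklevel=2,
        )
        return np.repeat(data, n_synthetic, axis=1)
    rng = np.random.default_rng(seed)
    k_eff = min(smote_k, t_rare - 1)
    nbr = _within_cluster_knn(data, k_eff)
    out = np.empty((g, n_synthetic))
    for t in range(n_synthetic):
        i = t % t_rare
        j = nbr[i, rng.integers(k_eff)]
        u = rng.uniform()
        out[:, t] = data[:, i] + u * (data[:, j] - data[:, i])
    return out


def center_undersample(data: np.ndarray, U: float = 0.8, seed: int = 0) -> np.ndarray:
    """Indices of cells retained from one major cluster.

    ``data`` is the genes x T_major block. Cells are ranked by Euclidean
    distance to the cluster centroid (mean vector), ascending, with ties
    broken by cell index; the first ``max(1, floor(U * T))`` are kept.
    Returned indices are in distance-rank order.
    """
    t = data.shape[1]
    centroid = data.mean(axis=1, keepdims=True)
    dist = np.linalg.norm(data - centroid, axis=0)
    order = np.argsort(dist, kind="stable")
    n_keep = max(1, int(np.floor(U * t)))
    return order[:n_keep]


def balance(
    m: ExpressionMatrix,
    lab: ClusterLabeling,
    plan: BalancePlan,
    seed: int = 0,
    mode: str = "both",
) -> BalancedDataset:
    """Apply the balancing plan to a log-normalized matrix.

    Output columns are the retained original cells in input order,
    followed by synthetic cells grouped by rare-cluster id. ``mode``
    selects which half of the strategy runs: ``both`` (default),
    ``over_only``, ``under_only`` or ``none``.
    """
    if mode not in BALANCE_MODES:
        raise ValueError(f"mode must be one of {BALANCE_MODES}, got {mode!r}")
    if m.n_cells != lab.c:
        raise ValueError("labels do not align with matrix columns")
    sizes = lab.sizes
    t_central = int(sizes[plan.central_cluster])
    rng = np.random.default_rng(seed)

    keep = np.ones(lab.c, dtype=bool)
    if mode in ("both", "under_only"):
        for cl in plan.major_clusters:
            members = np.flatnonzero(lab.labels == cl)
            retained = center_undersample(
                m.values[:, members], U=plan.retain_fraction,
                seed=int(rng.integers(2**31)),
            )
            drop = np.setdiff1d(members, members[retained])
            keep[drop] = False

    blocks = [m.values[:, keep]]
    labels = [lab.labels[keep]]
    provenance = [np.full(int(keep.sum()), "original", dtype=object)]

    if mode in ("both", "over_only"):
        for cl in plan.rare_clusters:
            members = np.flatnonzero(lab.labels == cl)
            n_syn = t_central - members.size
            syn = smote_oversample(
                m.values[:, members], n_syn, smote_k=plan.smote_k,
                seed=int(rng.integers(2**31)),
            )
            blocks.append(syn)
            labels.append(np.full(syn.shape[1], cl, dtype=int))
            provenance.append(np.full(syn.shape[1], "synthetic", dtype=object))

    return BalancedDataset(
        values=np.concatenate(blocks, axis=1),
        labels=np.concatenate(labels),
        provenance=np.concatenate(provenance),
    )
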
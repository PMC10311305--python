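"""Cell-label prediction: PCA, Euclidean k-NN graph, spectral clustering.

Cells are embedded with PCA on the log-normalized matrix (top 50
components by default, capped at ``min(n_components, c - 1, g)``), a
binary k-nearest-neighbor graph is built on the embedding (k = 15,
union-symmetrized), and the graph is partitioned by spectral clustering
(normalized Laplacian embedding + k-means assignment).

The number of clusters ``n`` is supplied by the user or, with
``n="auto"``, estimated by the largest eigengap of the normalized
Laplacian spectrum among 2..15 candidate cluster counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, laplacian
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA

from .data import ExpressionMatrix

__all__ = [
    "Embedding",
    "NeighborGraph",
    "ClusterLabeling",
    "pca_embed",
    "build_knn_graph",
    "spectral_partition",
    "estimate_n_clusters",
    "predict_labels",
]


@dataclass
class Embedding:
    """PCA coordinates: cells x components, variance-ordered."""

    coords: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """Binary, union-symmetrized k-NN adjacency with zero diagonal."""

    adjacency: sp.csr_matrix
    k: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class ClusterLabeling:
    """Per-cell integer cluster assignment.

    ``labels`` take values in ``0..n-1`` with cluster 0 the largest
    (ties resolved toward the lowest pre-relabeling id). ``h = c / n``
    is the reference size used downstream to pick the central cluster.
    """

    labels: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.labels.size == 0:
            raise ValueError("empty labeling")
        if self.labels.min() < 0 or self.labels.max() >= self.n:
            raise ValueError("labels out of range 0..n-1")

    @property
    def c(self) -> int:
        return self.labels.size

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n)

    @property
    def h(self) -> float:
        return self.c / self.n


def _relabel_by_size(labels: np.ndarray, n: int) -> np.ndarray:
    """Relabel so cluster 0 is the largest; ties -> lowest original label."""
    sizes = np.bincount(labels, minlength=n)
    order = sorted(range(n), key=lambda lab: (-sizes[lab], lab))
    mapping = np.empty(n, dtype=int)
    for new, old in enumerate(order):
        mapping[old] = new
    return mapping[labels]


def pca_embed(m: ExpressionMatrix, n_components: int = 50) -> Embedding:
    """Project mean-centered cells onto the top principal components.

    The component count is capped at ``min(n_components, c - 1, g)``.
    """
    if m.layer != "lognorm":
        raise ValueError("pca_embed expects a log-normalized matrix")
    c, g = m.n_cells, m.n_genes
    if c < 2:
        raise ValueError("PCA requires at least 2 cells")
    p = min(n_components, c - 1, g)
    # cells are the samples: operate on the transpose
    pca = PCA(n_components=p, svd_solver="full", random_state=0)
    coords = pca.fit_transform(m.values.T)
    return Embedding(coords=coords, explained_variance=pca.explained_variance_)


def _knn_indices(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbors per row, self excluded.

    Uses a stable argsort over exact pairwise distances so that ties at
    the k-th distance break deterministically by cell index.
    """
    c = coords.shape[0]
    sq = np.einsum("ij,ij->i", coords, coords)
    out = np.empty((c, k), dtype=int)
    for start in range(0, c, chunk):
        stop = min(start + chunk, c)
        block = coords[start:stop]
        d2 = sq[start:stop, None] - 2.0 * block @ coords.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        for i in range(start, stop):
            row = d2[i - start].copy()
            row[i] = np.inf  # exclude self
            order = np.argsort(row, kind="stable")
            out[i] = order[:k]
    return out


def build_knn_graph(e: Embedding, k: int = 15) -> NeighborGraph:
    """Binary k-NN graph on the embedding, union-symmetrized.

    Each cell is connected to its ``k`` nearest Euclidean neighbors
    (self excluded); an edge is kept if either endpoint selects the
    other. Raises if ``c <= k``.
    """
    c = e.n_cells
    if c <= k:
        raise ValueError(
            f"need more cells ({c}) than neighbors (k={k}); use a smaller k"
        )
    nbr = _knn_indices(e.coords, k)
    rows = np.repeat(np.arange(c), k)
    cols = nbr.ravel()
    adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(c, c))
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    adj.setdiag(0)
    adj.eliminate_zeros()
    return NeighborGraph(adjacency=adj, k=k)


def spectral_partition(gph: NeighborGraph, n: int, seed: int = 0) -> ClusterLabeling:
    """Partition the graph into ``n`` groups by spectral clustering.

    Normalized-Laplacian spectral embedding followed by seeded k-means
    (10 restarts). Labels are relabeled so cluster 0 is the largest.
    """
    c = gph.n_cells
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > c:
        raise ValueError(f"cannot split {c} cells into {n} clusters")
    if n == 1:
        return ClusterLabeling(labels=np.zeros(c, dtype=int), n=1)
    n_comp, _ = connected_components(gph.adjacency, directed=False)
    if n_comp > n:
        warnings.warn(
            f"graph has {n_comp} connected components but n={n}; "
            "proceeding with spectral clustering",
            stacklevel=2,
        )
    model = SpectralClustering(
        n_clusters=n,
        affinity="precomputed",
        assign_labels="kmeans",
        n_init=10,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Graph is not fully connected")
        labels = model.fit_predict(gph.adjacency)
    return ClusterLabeling(labels=_relabel_by_size(labels, n), n=n)


def estimate_n_clusters(gph: NeighborGraph, n_max: int = 15) -> int:
    """Eigengap heuristic on the normalized Laplacian spectrum.

    Returns the ``n`` in 2..n_max maximizing the gap between the n-th
    and (n+1)-th smallest eigenvalues.
    """
    c = gph.n_cells
    n_max = min(n_max, c - 1)
    need = n_max + 1
    lap = laplacian(gph.adjacency, normed=True)
    if c <= 3000:
        vals = np.linalg.eigvalsh(lap.toarray())[:need]
    else:
        vals = sp.linalg.eigsh(
            lap + 1e-9 * sp.identity(c), k=need, sigma=0, which="LM",
            return_eigenvectors=False,
        )
        vals = np.sort(vals)
    gaps = vals[2 : n_max + 1] - vals[1:n_max]  # gap after n-th eigenvalue, n=2..n_max
    return int(np.argmax(gaps)) + 2


def predict_labels(
    m: ExpressionMatrix,
    n: int | str = "auto",
    seed: int = 0,
    n_pcs: int = 50,
    knn_k: int = 15,
) -> ClusterLabeling:
    """Full label-prediction flow: PCA -> k-NN graph -> spectral clustering."""
    emb = pca_embed(m, n_components=n_pcs)
    gph = build_knn_graph(emb, k=knn_k)
    if n == "auto":
        n = estimate_n_clusters(gph)
    elif not isinstance(n, (int, np.integer)):
        raise ValueError(f"n must be an integer or 'auto', got {n!r}")
    return spectral_partition(gph, int(n), seed=seed)
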
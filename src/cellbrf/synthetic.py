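"""Seeded synthetic scRNA-seq count data with known cluster structure.

The generator emulates the features the pipeline is sensitive to:
negative-binomial counts (overdispersed, zero-inflated at low means),
a designated set of informative marker genes whose mean is shifted
``2^LFC``-fold in one assigned cluster (assignment round-robin so every
cluster — including rare ones — carries markers), tunable cluster-size
imbalance through the cluster proportions, and optional exact-duplicate
genes for exercising redundancy pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``cluster_props`` must sum to 1; cluster sizes are the proportions
    scaled to ``n_cells`` and rounded (largest remainders get the spare
    cells). Informative gene ``i`` is upregulated ``2**log_fold_change``-
    fold in cluster ``i mod n_clusters``. ``n_duplicate_pairs`` extra
    genes are exact copies of the first informative genes.
    """

    n_cells: int = 500
    n_genes: int = 200
    n_clusters: int = 3
    cluster_props: tuple[float, ...] | None = None
    n_informative: int = 20
    log_fold_change: float = 2.0
    nb_dispersion: float = 10.0
    base_mean: float = 5.0
    n_duplicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_props is None:
            self.cluster_props = tuple([1.0 / self.n_clusters] * self.n_clusters)
        self.cluster_props = tuple(float(p) for p in self.cluster_props)
        if len(self.cluster_props) != self.n_clusters:
            raise ValueError("cluster_props length must equal n_clusters")
        if abs(sum(self.cluster_props) - 1.0) > 1e-8:
            raise ValueError("cluster_props must sum to 1")
        if min(self.cluster_props) <= 0:
            raise ValueError("cluster_props must be positive")
        if self.n_informative + 2 * self.n_duplicate_pairs > self.n_genes:
            raise ValueError("too many informative/duplicate genes for n_genes")
        if self.n_duplicate_pairs > self.n_informative:
            raise ValueError("more duplicate pairs than informative genes")
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        if self.log_fold_change < 0 or self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("invalid effect-size / distribution parameters")


def _rounded_sizes(props: tuple[float, ...], n_cells: int) -> np.ndarray:
    """Largest-remainder rounding of proportions to integer sizes >= 1."""
    raw = np.asarray(props) * n_cells
    sizes = np.floor(raw).astype(int)
    short = n_cells - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:short]] += 1
    if (sizes == 0).any():
        # every cluster must exist: steal from the largest
        for cl in np.flatnonzero(sizes == 0):
            sizes[np.argmax(sizes)] -= 1
            sizes[cl] += 1
    return sizes


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with given mean and size (dispersion) r.

    Variance is mean + mean^2 / r; small r = strong overdispersion.
    """
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, np.ndarray, list[str], list[list[str]]]:
    """Generate one dataset.

    Returns ``(matrix, true_labels, informative_gene_ids,
    duplicate_groups)`` where the matrix is raw counts (genes x cells),
    labels align with its columns, and each duplicate group lists the
    ids of genes with identical rows. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _rounded_sizes(spec.cluster_props, spec.n_cells)
    labels = np.repeat(np.arange(spec.n_clusters), sizes)

    # mean matrix: genes x cells, base mean everywhere, marker genes
    # boosted in their assigned cluster
    mean = np.full((spec.n_genes, spec.n_cells), float(spec.base_mean))
    informative = list(range(spec.n_informative))
    for gi in informative:
        cl = gi % spec.n_clusters
        mean[gi, labels == cl] = spec.base_mean * 2.0**spec.log_fold_change
    counts = _nb_counts(rng, mean, spec.nb_dispersion).astype(float)

    # exact-duplicate genes overwrite the last noise rows
    duplicate_groups: list[list[str]] = []
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    for d in range(spec.n_duplicate_pairs):
        src = d  # copy the d-th informative gene
        dst = spec.n_genes - 1 - d
        counts[dst] = counts[src]
        duplicate_groups.append([gene_ids[src], gene_ids[dst]])

    # shuffle cell order so clusters are not contiguous
    perm = rng.permutation(spec.n_cells)
    counts = counts[:, perm]
    labels = labels[perm]

    cell_ids = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    m = ExpressionMatrix(counts, gene_ids, cell_ids, layer="raw")
    informative_ids = [gene_ids[i] for i in informative]
    return m, labels, informative_ids, duplicate_groups
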
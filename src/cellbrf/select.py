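"""Final gene-set extraction: three-sigma cut plus redundancy pruning.

Genes whose forest importance is at least ``mu + 3 sigma`` of the
importance distribution form an ordered candidate list (importance
descending). Redundant genes are then removed by a sequential scan:
for each surviving anchor gene G_i, every later surviving gene G_j with
Pearson correlation S_ij above a dynamic threshold

    h' = v + v' / (L + 1)

is dropped, where v (default 0.8) is the base correlation threshold,
v' (default 0.1) tightens it for the highest-importance anchors, and L
is the number of surviving genes after the current anchor. The signed
correlation is compared (anti-correlated genes are never removed).
Correlations are computed on the log-normalized matrix over all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix
from .importance import ImportanceVector

__all__ = [
    "SelectionConfig",
    "RemovalRecord",
    "GeneSelection",
    "three_sigma_cut",
    "dynamic_threshold",
    "redundancy_prune",
    "select_features",
]


@dataclass
class SelectionConfig:
    """Correlation-pruning parameters (v: base threshold, v_prime: boost)."""

    v: float = 0.8
    v_prime: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.v < 1:
            raise ValueError("v must be in (0, 1)")
        if self.v_prime < 0:
            raise ValueError("v_prime must be non-negative")


@dataclass
class RemovalRecord:
    """Audit entry: gene removed for redundancy with a stronger anchor."""

    gene: str
    removed_by: str
    correlation: float
    threshold: float


@dataclass
class GeneSelection:
    """Final ordered gene set plus the removal audit trail."""

    ordered_genes: list[str]
    removed: list[RemovalRecord]
    importances: dict[str, float] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.ordered_genes)


def three_sigma_cut(
    imp: ImportanceVector, gene_ids: list[str] | None = None
) -> list[int]:
    """Indices of genes with importance >= mu + 3 sigma, sorted by
    importance descending (ties by gene index ascending).

    If no gene clears the cut, falls back to the single top-importance
    gene with a warning.
    """
    f = imp.f
    cutoff = imp.mu + 3.0 * imp.sigma
    idx = np.flatnonzero(f >= cutoff)
    if idx.size == 0:
        warnings.warn(
            "no gene reaches mu + 3 sigma; falling back to the top gene",
            stacklevel=2,
        )
        idx = np.array([int(np.argmax(f))])
    # stable sort on descending importance; ties keep ascending gene index
    order = np.argsort(-f[idx], kind="stable")
    return [int(i) for i in idx[order]]


def dynamic_threshold(cfg: SelectionConfig, L: int) -> float:
    """Correlation threshold h' = v + v'/(L+1) for L genes still pending."""
    if L < 0:
        raise ValueError("L must be non-negative")
    return cfg.v + cfg.v_prime / (L + 1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 (by convention) if either vector is constant."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def redundancy_prune(
    m: ExpressionMatrix,
    genes: list[str],
    cfg: SelectionConfig | None = None,
    importances: dict[str, float] | None = None,
) -> GeneSelection:
    """Sequentially drop genes too correlated with a stronger anchor.

    ``genes`` must be ordered by importance descending. Anchors are
    scanned in order over surviving genes; at each anchor the threshold
    h'(L) is evaluated with L = number of surviving genes after the
    anchor, and every later surviving gene whose signed Pearson
    correlation with the anchor exceeds h' is removed. Removed genes
    never become anchors. Zero-variance genes correlate 0 with
    everything (warned) and are never removed for redundancy.
    """
    if cfg is None:
        cfg = SelectionConfig()
    if m.layer != "lognorm":
        raise ValueError("pruning correlations use the log-normalized matrix")
    rows = {gid: m.values[m.gene_index(gid)] for gid in genes}
    for gid, row in rows.items():
        if np.ptp(row) == 0:
            warnings.warn(
                f"gene {gid!r} has zero variance; correlations set to 0",
                stacklevel=2,
            )
    surviving = list(genes)
    removed: list[RemovalRecord] = []
    pos = 0
    while pos < len(surviving):
        anchor = surviving[pos]
        L = len(surviving) - pos - 1
        h_prime = dynamic_threshold(cfg, L)
        kept_tail = []
        for gid in surviving[pos + 1 :]:
            s = _pearson(rows[anchor], rows[gid])
            if s > h_prime:
                removed.append(
                    RemovalRecord(
                        gene=gid, removed_by=anchor,
                        correlation=s, threshold=h_prime,
                    )
                )
            else:
                kept_tail.append(gid)
        surviving = surviving[: pos + 1] + kept_tail
        pos += 1
    return GeneSelection(
        ordered_genes=surviving,
        removed=removed,
        importances=dict(importances or {}),
    )


def select_features(
    m: ExpressionMatrix,
    imp: ImportanceVector,
    cfg: SelectionConfig | None = None,
) -> GeneSelection:
    """Three-sigma cut followed by redundancy pruning."""
    if imp.n_genes != m.n_genes:
        raise ValueError("importance vector does not match matrix genes")
    idx = three_sigma_cut(imp)
    genes = [m.gene_ids[i] for i in idx]
    importances = {m.gene_ids[i]: float(imp.f[i]) for i in idx}
    return redundancy_prune(m, genes, cfg=cfg, importances=importances)
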
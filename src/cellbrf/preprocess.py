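"""Gene filtering and log-normalization.

The preprocessing flow for a raw genes x cells count matrix ``X``:

1. remove genes expressed (value > 0) in fewer than ``min_cells`` cells;
2. remove cells with zero total count (size factors undefined for them);
3. divide each cell by its size factor — library size over the median
   library size — and transform ``X' = log2(X_norm + 1)``.

Size-factor scaling relative to the median depth is the common scRNA-seq
convention; the median of the returned factors is exactly 1, so a dataset
with uniform depth is left untouched by normalization.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import ExpressionMatrix

__all__ = [
    "filter_low_expression",
    "drop_zero_depth_cells",
    "compute_size_factors",
    "normalize_and_log",
    "preprocess",
]


def filter_low_expression(m: ExpressionMatrix, min_cells: int = 3) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in at least ``min_cells`` cells.

    Gene order is preserved; cells are untouched. Raises ``ValueError``
    if no gene survives (empty feature space).
    """
    if m.layer != "raw":
        raise ValueError("filter_low_expression expects a raw-layer matrix")
    n_expressing = (m.values > 0).sum(axis=1)
    keep = np.flatnonzero(n_expressing >= min_cells)
    if keep.size == 0:
        raise ValueError(
            f"all {m.n_genes} genes are expressed in fewer than {min_cells} "
            "cells; empty feature space"
        )
    if keep.size == m.n_genes:
        return m
    return m.subset_genes(keep)


def drop_zero_depth_cells(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove cells whose total count is zero, with a warning."""
    depths = m.values.sum(axis=0)
    keep = np.flatnonzero(depths > 0)
    if keep.size == m.n_cells:
        return m
    dropped = [m.cell_ids[i] for i in np.flatnonzero(depths == 0)]
    warnings.warn(
        f"removing {len(dropped)} zero-depth cell(s): {dropped[:5]}...",
        stacklevel=2,
    )
    if keep.size == 0:
        raise ValueError("every cell has zero total count")
    return m.subset_cells(keep)


def compute_size_factors(m: ExpressionMatrix) -> np.ndarray:
    """Per-cell size factors: sequencing depth over the median depth.

    ``depth(cell)`` is the column sum. The median of the returned vector
    is 1 by construction. A zero-depth cell is an error — remove it first
    with :func:`drop_zero_depth_cells`.
    """
    if m.layer != "raw":
        raise ValueError("size factors are computed from raw counts")
    depths = m.values.sum(axis=0)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        bad = [m.cell_ids[i] for i in zero]
        raise ValueError(f"cell(s) with zero total count: {bad[:10]}")
    return depths / np.median(depths)


def normalize_and_log(m: ExpressionMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Scale each cell by its size factor and apply log2(x + 1)."""
    if m.layer != "raw":
        raise ValueError("normalize_and_log expects a raw-layer matrix")
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.n_cells,):
        raise ValueError(
            f"expected {m.n_cells} size factors, got shape {factors.shape}"
        )
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    values = np.log2(m.values / factors[np.newaxis, :] + 1.0)
    return ExpressionMatrix(values, list(m.gene_ids), list(m.cell_ids), layer="lognorm")


def preprocess(m: ExpressionMatrix, min_cells: int = 3) -> ExpressionMatrix:
    """Full preprocessing: gene filter, zero-depth removal, log-normalize."""
    m = filter_low_expression(m, min_cells=min_cells)
    m = drop_zero_depth_cells(m)
    factors = compute_size_factors(m)
    return normalize_and_log(m, factors)
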
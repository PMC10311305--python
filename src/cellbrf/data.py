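"""Core expression-matrix container.

The internal orientation is genes x cells (genes in rows), matching the
usual deposition format of count matrices. Readers that receive
cells x genes input transpose on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense non-negative float array of shape ``(g, c)``.
    gene_ids
        Unique gene identifiers, length ``g``.
    cell_ids
        Unique cell identifiers, length ``c``.
    layer
        ``"raw"`` for counts (or any non-negative raw values),
        ``"lognorm"`` after size-factor normalization and log2(x+1).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        g, c = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} gene rows")
        if len(self.cell_ids) != c:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {c} cell columns")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != c:
            raise ValueError("duplicate cell ids")
        if self.layer not in ("raw", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf")
        if (self.values < 0).any():
            raise ValueError("values contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene row indices."""
        index = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            values=self.values[index],
            gene_ids=[self.gene_ids[i] for i in index],
            cell_ids=list(self.cell_ids),
            layer=self.layer,
        )

    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given cell column indices."""
        index = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, index],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            layer=self.layer,
        )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
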
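"""Readers and writers for expression matrices.

Supported input layouts:

* delimited text (CSV/TSV): genes in rows, header row of cell ids,
  first column of gene ids (``transpose=True`` for cells x genes files);
* Matrix Market: ``<stem>.mtx`` with sidecar name files
  ``<stem>_genes.txt`` / ``<stem>_barcodes.txt`` (one id per line);
* 10x-style directory: ``matrix.mtx`` plus ``features.tsv`` (or
  ``genes.tsv``) and ``barcodes.tsv``; ``.gz`` variants accepted.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import ExpressionMatrix

__all__ = [
    "read_csv",
    "read_mtx",
    "read_10x",
    "read_matrix",
    "write_csv",
    "write_mtx",
]


def read_csv(
    path: str | Path, sep: str | None = None, transpose: bool = False
) -> ExpressionMatrix:
    """Read a delimited genes x cells matrix (ids in row/column headers)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        layer="raw",
    )


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find(path_dir: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (path_dir / name, path_dir / f"{name}.gz"):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} found in {path_dir}")


def read_mtx(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read ``<stem>.mtx`` with ``<stem>_genes.txt`` / ``<stem>_barcodes.txt``."""
    path = Path(path)
    stem = path.with_suffix("")
    mat = scipy.io.mmread(path)
    genes = _read_lines(Path(f"{stem}_genes.txt"))
    cells = _read_lines(Path(f"{stem}_barcodes.txt"))
    values = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    if transpose:
        values = values.T
    return ExpressionMatrix(values, genes, cells, layer="raw")


def read_10x(path_dir: str | Path) -> ExpressionMatrix:
    """Read a 10x-style directory (matrix.mtx, features/genes.tsv, barcodes.tsv)."""
    path_dir = Path(path_dir)
    mtx = _find(path_dir, ["matrix.mtx"])
    opener = gzip.open if mtx.suffix == ".gz" else open
    with opener(mtx, "rb") as fh:
        mat = scipy.io.mmread(fh)
    genes = _read_lines(_find(path_dir, ["features.tsv", "genes.tsv"]))
    cells = _read_lines(_find(path_dir, ["barcodes.tsv"]))
    values = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    return ExpressionMatrix(values, genes, cells, layer="raw")


def read_matrix(
    path: str | Path, fmt: str = "csv", transpose: bool = False
) -> ExpressionMatrix:
    """Dispatch on format name: ``csv``, ``mtx`` or ``10x``."""
    if fmt == "csv":
        return read_csv(path, transpose=transpose)
    if fmt == "mtx":
        return read_mtx(path, transpose=transpose)
    if fmt == "10x":
        return read_10x(path)
    raise ValueError(f"unknown format {fmt!r}; expected csv, mtx or 10x")


def write_csv(m: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    """Write the matrix as delimited text, genes in rows."""
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
    df.to_csv(path, sep=sep)


def write_mtx(m: ExpressionMatrix, path: str | Path) -> None:
    """Write ``<stem>.mtx`` plus gene/barcode sidecar files."""
    path = Path(path)
    stem = path.with_suffix("")
    scipy.io.mmwrite(str(path.with_suffix("")) + ".mtx", sp.coo_matrix(m.values))
    Path(f"{stem}_genes.txt").write_text("\n".join(m.gene_ids) + "\n")
    Path(f"{stem}_barcodes.txt").write_text("\n".join(m.cell_ids) + "\n")
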
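"""Expression-matrix container and readers/writers for standard formats.

A single in-memory convention is used everywhere: cells in rows, genes in
columns, non-negative values (FPKM/CPM/UMI counts).  On-disk layout may be
either orientation for delimited text, or a Matrix Market triplet with
features/barcodes sidecar files (10x style, genes x cells).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError

__all__ = ["ExpressionMatrix", "load_expression", "save_expression"]


@dataclass
class ExpressionMatrix:
    """Non-negative m cells x n genes expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense ``(m, n)`` float array, cells in rows.  Entries must be
        finite and non-negative.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    unit_label
        Free-text description of the expression unit (e.g. ``"UMI"``).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    unit_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise FormatError("expression matrix must be 2-dimensional")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise FormatError(f"need at least 2 cells and 2 genes, got {m}x{n}")
        if len(self.cell_ids) != m or len(self.gene_ids) != n:
            raise FormatError("identifier lists do not match matrix shape")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains missing/non-finite values")
        if (self.values < 0).any():
            raise FormatError("expression matrix contains negative entries")
        if len(set(self.cell_ids)) != m:
            raise FormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n:
            raise FormatError("duplicate gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        """Return a copy restricted to the given genes.

        ``keep`` may be a boolean mask of length n, integer indices, or a
        list of gene ids (order preserved as given).
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[str(g)] for g in keep], dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            unit_label=self.unit_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def _read_delimited(path: str, layout: str) -> ExpressionMatrix:
    sep = {".csv": ",", ".tsv": "\t", ".txt": "\t"}.get(
        os.path.splitext(path)[1].lower(), None
    )
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python" if sep is None else "c")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot read delimited matrix {path!r}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"missing values in {path!r}")
    if layout == "genes-by-cells":
        df = df.T
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
    )


def _sidecar(path: str, names: tuple[str, ...]) -> str:
    d = os.path.dirname(os.path.abspath(path))
    for name in names:
        p = os.path.join(d, name)
        if os.path.exists(p):
            return p
    raise FormatError(f"missing sidecar file (tried {names}) next to {path!r}")


def _read_ids(path: str) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None)
    # 10x features files may carry extra columns (symbol, feature type)
    return [str(v) for v in ids.iloc[:, 0]]


def _read_mtx(path: str, layout: str) -> ExpressionMatrix:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read Matrix Market file {path!r}: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.tocsr()
    genes = _read_ids(_sidecar(path, ("genes.tsv", "features.tsv")))
    cells = _read_ids(_sidecar(path, ("barcodes.tsv",)))
    if layout == "genes-by-cells":
        rows, cols = genes, cells
    else:
        rows, cols = cells, genes
    if mat.shape != (len(rows), len(cols)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells, layout={layout})"
        )
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if layout == "genes-by-cells":
        dense = dense.T
    return ExpressionMatrix(values=dense, cell_ids=cells, gene_ids=genes)


def load_expression(
    path: str,
    layout: str = "cells-by-genes",
    format: str | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix in cells x genes orientation.

    Parameters
    ----------
    path
        Delimited text file (header row + id column) or ``.mtx`` file with
        ``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` sidecars.
    layout
        On-disk orientation: ``"cells-by-genes"`` or ``"genes-by-cells"``.
        MTX triplets from 10x pipelines are genes-by-cells.
    format
        ``"delimited"`` or ``"mtx-triplet"``; inferred from the extension
        when omitted.
    """
    if layout not in ("cells-by-genes", "genes-by-cells"):
        raise ValueError(f"unknown layout {layout!r}")
    if not os.path.exists(path):
        raise FormatError(f"input file not found: {path!r}")
    if format is None:
        format = "mtx-triplet" if path.lower().endswith(".mtx") else "delimited"
    if format == "mtx-triplet":
        return _read_mtx(path, layout)
    if format == "delimited":
        return _read_delimited(path, layout)
    raise ValueError(f"unknown format {format!r}")


def save_expression(
    x: ExpressionMatrix,
    path: str,
    layout: str = "cells-by-genes",
    format: str | None = None,
) -> None:
    """Write a matrix back out in the given format/layout (inverse of load)."""
    if format is None:
        format = "mtx-triplet" if path.lower().endswith(".mtx") else "delimited"
    if format == "mtx-triplet":
        d = os.path.dirname(os.path.abspath(path))
        os.makedirs(d, exist_ok=True)
        sparse = scipy.sparse.csr_matrix(
            x.values.T if layout == "genes-by-cells" else x.values
        )
        scipy.io.mmwrite(path, sparse)
        with open(os.path.join(d, "features.tsv"), "w") as fh:
            fh.write("\n".join(x.gene_ids) + "\n")
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(x.cell_ids) + "\n")
        return
    df = x.to_dataframe()
    if layout == "genes-by-cells":
        df = df.T
    sep = "," if path.lower().endswith(".csv") else "\t"
    df.to_csv(path, sep=sep)
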
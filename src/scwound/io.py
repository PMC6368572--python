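"""Input/output for the pipeline: UMI count containers, 10x-style MTX bundles,
dense TSV matrices, and result tables.

The canonical in-memory orientation is cells x genes.  The 10x MatrixMarket
dialect stores genes x cells on disk; readers transpose at the boundary so the
rest of the package never sees the on-disk orientation.
"""

from __future__ import annotations

import dataclasses
import gzip
import io as _io
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "UmiMatrix",
    "FormatError",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_dense_tsv",
    "write_results",
    "MITO_PREFIX",
]

#: Default mitochondrial symbol prefix (mouse nomenclature, e.g. "mt-Co1").
MITO_PREFIX = re.compile(r"^mt-", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an on-disk input violates the expected format."""


@dataclasses.dataclass
class UmiMatrix:
    """Integer UMI count matrix, cells x genes, with identifiers.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, one row per cell.  Sparse input is
        accepted and densified; desk-scale matrices are kept dense.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    gene_symbols
        Display symbols (may repeat); defaults to ``gene_ids``.
    mito_flag
        Boolean per gene; derived from ``gene_symbols`` via *mito_pattern*
        when not given.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray = None
    mito_flag: np.ndarray = None

    def __post_init__(self):
        if sp.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integer-valued")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts must be nonnegative")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids")
        if self.gene_symbols is None:
            self.gene_symbols = self.gene_ids.copy()
        else:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
            if len(self.gene_symbols) != n_genes:
                raise FormatError("gene_symbols length mismatch")
        if self.mito_flag is None:
            self.mito_flag = np.array(
                [bool(MITO_PREFIX.match(str(s))) for s in self.gene_symbols]
            )
        else:
            self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
            if len(self.mito_flag) != n_genes:
                raise FormatError("mito_flag length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def genes_detected(self) -> np.ndarray:
        """Number of genes with nonzero count per cell."""
        return (self.counts > 0).sum(axis=1)

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's counts in mitochondrial-flagged genes."""
        totals = self.cell_totals().astype(float)
        mito = self.counts[:, self.mito_flag].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def subset(self, cells=None, genes=None) -> "UmiMatrix":
        """Return a new matrix restricted to the given cell/gene index arrays."""
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        return UmiMatrix(
            counts=self.counts[np.ix_(ci, gi)],
            cell_ids=self.cell_ids[ci],
            gene_ids=self.gene_ids[gi],
            gene_symbols=self.gene_symbols[gi],
            mito_flag=self.mito_flag[gi],
        )

    def gene_index(self, symbol: str) -> int:
        """Locate a gene by symbol, case-insensitively; ambiguity is an error."""
        matches = [
            i for i, s in enumerate(self.gene_symbols)
            if str(s).lower() == symbol.lower()
        ]
        if not matches:
            raise KeyError(f"gene symbol not found: {symbol!r}")
        if len(matches) > 1:
            raise KeyError(f"gene symbol ambiguous: {symbol!r} ({len(matches)} hits)")
        return matches[0]


def _find(path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = path / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"no {stems[0]}(.gz) (or alternatives {stems[1:]}) under {path}"
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_mtx_bundle(path) -> UmiMatrix:
    """Read a 10x-style bundle (matrix.mtx + barcodes.tsv + features/genes.tsv).

    The on-disk matrix is genes x cells (10x dialect) and is transposed so the
    returned :class:`UmiMatrix` is cells x genes.  Files may be gzipped.
    Mitochondrial genes are flagged by the "mt-" symbol prefix.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"bundle directory not found: {path}")
    mtx_path = _find(path, ["matrix.mtx"])
    bc_path = _find(path, ["barcodes.tsv"])
    ft_path = _find(path, ["features.tsv", "genes.tsv"])

    with _open_text(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(_io.StringIO(fh.read()))
        except Exception as exc:
            raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}")
    mat = sp.coo_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.array_equal(mat.data, np.round(mat.data)):
            raise FormatError(f"non-integer entries in {mtx_path}")
        mat = mat.astype(np.int64)

    with _open_text(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(ft_path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    gene_ids = [r[0] for r in rows]
    gene_symbols = [r[1] if len(r) > 1 else r[0] for r in rows]

    n_genes_disk, n_cells_disk = mat.shape
    if n_genes_disk != len(gene_ids):
        raise FormatError(
            f"matrix header says {n_genes_disk} genes but features file "
            f"{ft_path.name} has {len(gene_ids)} lines"
        )
    if n_cells_disk != len(barcodes):
        raise FormatError(
            f"matrix header says {n_cells_disk} cells but barcodes file "
            f"{bc_path.name} has {len(barcodes)} lines"
        )
    counts = np.asarray(mat.T.todense())
    return UmiMatrix(
        counts=counts,
        cell_ids=np.array(barcodes, dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
        gene_symbols=np.array(gene_symbols, dtype=object),
    )


def write_mtx_bundle(m: UmiMatrix, path) -> None:
    """Write *m* as a 10x-style bundle (genes x cells on disk, uncompressed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(m.counts.T)
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    with open(path / "barcodes.tsv", "w") as fh:
        fh.writelines(str(b) + "\n" for b in m.cell_ids)
    with open(path / "features.tsv", "w") as fh:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")


def read_dense_tsv(path) -> UmiMatrix:
    """Read a dense cells x genes TSV (first column = cell id, header = genes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dense matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"non-integer entries in {path}")
    return UmiMatrix(
        counts=values.astype(np.int64),
        cell_ids=df.index.to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with stable column order.

    Floats are rendered with 8 significant digits so a parse-back reproduces
    values to well within any tolerance used downstream.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.8g")
    except OSError as exc:
        raise OSError(f"cannot write results table to {path}: {exc}")
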
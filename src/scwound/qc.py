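"""Cell and gene quality control, library-size normalization, and highly
variable gene selection.

Two QC dialects are implemented, matching the two capture chemistries the
analysis supports:

* droplet (3'-end, high cell number / shallow depth): keep cells with
  total UMI < 8000 (strict), detected genes < 2500 (strict), and
  mitochondrial fraction <= 8% (inclusive — "no more than 8%").
* full-length (microfluidic, few cells / deep): remove cells with detected
  genes > 11,000 or mitochondrial fraction > 15% (both strict-exceed), then
  remove genes expressed in fewer than 3 of the surviving cells.

Boundary strictness follows the wording of the source protocol literally and
is asserted in the test suite so it stays auditable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import UmiMatrix

__all__ = [
    "QcParams",
    "HvgParams",
    "ExprMatrix",
    "QcReport",
    "apply_droplet_qc",
    "apply_fulllength_qc",
    "normalize_log",
    "select_hvg",
]


@dataclasses.dataclass
class QcParams:
    droplet_max_umi: int = 8000
    droplet_max_genes: int = 2500
    droplet_max_mito_frac: float = 0.08
    fulllength_max_genes: int = 11000
    fulllength_max_mito_frac: float = 0.15
    min_cells_per_gene: int = 3

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclasses.dataclass
class HvgParams:
    n_expr_bins: int = 20
    min_mean: float = 0.01
    min_dispersion: float = 1.0
    #: when False, apply min_dispersion to the raw (un-normalized) dispersion
    use_bin_normalized: bool = True

    def __post_init__(self):
        if self.n_expr_bins < 2:
            raise ValueError("n_expr_bins must be >= 2")


@dataclasses.dataclass
class QcReport:
    """Per-cell keep/remove decisions with reasons, plus removed genes."""

    cell_table: pd.DataFrame  # columns: cell, kept, reason
    removed_genes: list

    @property
    def n_kept(self) -> int:
        return int(self.cell_table["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.cell_table["kept"]).sum())


@dataclasses.dataclass
class ExprMatrix:
    """Library-size normalized, log-transformed expression (cells x genes).

    ``values[i, g] = ln(1 + counts[i, g] * scale_factor / total_i)``.
    ``norm_counts`` keeps the pre-log normalized counts, which mean/dispersion
    statistics are computed on (variance/mean is a count-scale statistic).
    """

    values: np.ndarray
    norm_counts: np.ndarray
    scale_factor: float
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    log_base: str = "e"

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbol: str) -> int:
        matches = [
            i for i, s in enumerate(self.gene_symbols)
            if str(s).lower() == symbol.lower()
        ]
        if not matches:
            raise KeyError(f"gene symbol not found: {symbol!r}")
        if len(matches) > 1:
            raise KeyError(f"gene symbol ambiguous: {symbol!r}")
        return matches[0]


def _reason_string(flags: dict) -> str:
    reasons = [name for name, bad in flags.items() if bad]
    return "+".join(reasons) if reasons else ""


def apply_droplet_qc(m: UmiMatrix, p: QcParams | None = None):
    """Droplet-chemistry cell QC.

    A cell is kept iff total UMI < droplet_max_umi AND detected genes <
    droplet_max_genes AND mito fraction <= droplet_max_mito_frac.  Genes are
    left untouched.  Returns ``(filtered UmiMatrix, QcReport)``.
    """
    p = p or QcParams()
    if m.n_cells == 0:
        raise ValueError("matrix has no cells")
    totals = m.cell_totals()
    genes = m.genes_detected()
    mito = m.mito_fraction()

    rows = []
    keep = np.zeros(m.n_cells, dtype=bool)
    for i in range(m.n_cells):
        flags = {
            "umi": totals[i] >= p.droplet_max_umi,
            "genes": genes[i] >= p.droplet_max_genes,
            "mito": mito[i] > p.droplet_max_mito_frac,
        }
        keep[i] = not any(flags.values())
        rows.append((m.cell_ids[i], keep[i], _reason_string(flags)))
    if not keep.any():
        warnings.warn("droplet QC removed every cell", stacklevel=2)
    report = QcReport(
        cell_table=pd.DataFrame(rows, columns=["cell", "kept", "reason"]),
        removed_genes=[],
    )
    return m.subset(cells=np.where(keep)[0]), report


def apply_fulllength_qc(m: UmiMatrix, p: QcParams | None = None):
    """Full-length-chemistry QC: cell pass, then gene pass on surviving cells.

    Cells with detected genes > fulllength_max_genes or mito fraction >
    fulllength_max_mito_frac are removed; afterwards genes expressed in fewer
    than min_cells_per_gene of the remaining cells are removed.  The gene pass
    runs on the post-cell-QC matrix, so a gene can be lost because its
    supporting cells failed QC.
    """
    p = p or QcParams()
    if m.n_cells == 0:
        raise ValueError("matrix has no cells")
    genes_det = m.genes_detected()
    mito = m.mito_fraction()

    rows = []
    keep = np.zeros(m.n_cells, dtype=bool)
    for i in range(m.n_cells):
        flags = {
            "genes": genes_det[i] > p.fulllength_max_genes,
            "mito": mito[i] > p.fulllength_max_mito_frac,
        }
        keep[i] = not any(flags.values())
        rows.append((m.cell_ids[i], keep[i], _reason_string(flags)))
    if not keep.any():
        warnings.warn("full-length QC removed every cell", stacklevel=2)
        empty = m.subset(cells=np.where(keep)[0])
        return empty, QcReport(
            cell_table=pd.DataFrame(rows, columns=["cell", "kept", "reason"]),
            removed_genes=list(m.gene_ids),
        )
    kept_cells = m.subset(cells=np.where(keep)[0])
    cells_per_gene = (kept_cells.counts > 0).sum(axis=0)
    gene_keep = cells_per_gene >= p.min_cells_per_gene
    removed_genes = list(kept_cells.gene_ids[~gene_keep])
    report = QcReport(
        cell_table=pd.DataFrame(rows, columns=["cell", "kept", "reason"]),
        removed_genes=removed_genes,
    )
    return kept_cells.subset(genes=np.where(gene_keep)[0]), report


def normalize_log(m: UmiMatrix, scale_factor: float = 10_000.0) -> ExprMatrix:
    """Library-size normalize to *scale_factor* counts per cell and log1p.

    Raises on zero-total cells: QC must run first so every cell carries counts.
    """
    totals = m.cell_totals().astype(float)
    if (totals == 0).any():
        n_zero = int((totals == 0).sum())
        raise ValueError(
            f"{n_zero} cells have zero total counts; apply QC before normalizing"
        )
    norm = m.counts * (scale_factor / totals[:, None])
    return ExprMatrix(
        values=np.log1p(norm),
        norm_counts=norm,
        scale_factor=scale_factor,
        cell_ids=m.cell_ids.copy(),
        gene_ids=m.gene_ids.copy(),
        gene_symbols=m.gene_symbols.copy(),
    )


def select_hvg(e: ExprMatrix, p: HvgParams | None = None):
    """Select highly variable genes by binned dispersion.

    Per gene, mean and dispersion (= variance / mean) are computed on the
    normalized pre-log counts.  Genes are ranked by mean into ``n_expr_bins``
    equal-count bins (ties broken by gene id); within each bin the median
    dispersion defines a normalized dispersion ``disp / bin_median``.  A gene
    is selected iff mean > min_mean AND normalized dispersion >
    min_dispersion (both strict).

    Returns ``(list of selected gene ids, per-gene dispersion table)``.
    """
    p = p or HvgParams()
    x = e.norm_counts
    means = x.mean(axis=0)
    n_nonzero_mean = int((means > 0).sum())
    if n_nonzero_mean < p.n_expr_bins:
        raise ValueError(
            f"need >= {p.n_expr_bins} genes with nonzero mean, have {n_nonzero_mean}"
        )
    var = x.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(means > 0, var / np.where(means > 0, means, 1.0), 0.0)

    # equal-count bins by mean rank; ties broken by gene id for determinism
    order = np.lexsort((e.gene_ids.astype(str), means))
    n_genes = len(means)
    bin_of = np.empty(n_genes, dtype=int)
    edges = np.linspace(0, n_genes, p.n_expr_bins + 1).astype(int)
    for b in range(p.n_expr_bins):
        bin_of[order[edges[b]:edges[b + 1]]] = b

    norm_disp = np.zeros(n_genes)
    for b in range(p.n_expr_bins):
        idx = bin_of == b
        med = np.median(disp[idx])
        if med == 0:
            warnings.warn(
                f"expression bin {b} has zero median dispersion; its genes get "
                "normalized dispersion 0",
                stacklevel=2,
            )
            norm_disp[idx] = 0.0
        else:
            norm_disp[idx] = disp[idx] / med

    criterion = norm_disp if p.use_bin_normalized else disp
    selected = (means > p.min_mean) & (criterion > p.min_dispersion)
    table = pd.DataFrame(
        {
            "gene": e.gene_ids,
            "mean": means,
            "dispersion": disp,
            "norm_dispersion": norm_disp,
            "bin": bin_of,
            "selected": selected,
        }
    )
    return list(e.gene_ids[selected]), table
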
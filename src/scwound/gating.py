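"""Threshold-based marker positivity and multi-marker gating.

Cells are called positive for a marker when their normalized UMI (nUMI)
count strictly exceeds a threshold; a multi-marker gate requires every
marker to pass (AND rule).  The default selection threshold is 0 (any
expression); stringent display gates use > 2.  nUMI scales each cell's
counts to the median library size, so zeros are preserved and positivity at
threshold 0 is unchanged by normalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import UmiMatrix
from .pseudotime import PseudotimeAssignment, bin_composition

__all__ = [
    "GateSpec",
    "GateResult",
    "normalize_numi",
    "gate_multi",
    "enrichment_by_cluster",
    "detect_hybrid_bins",
    "fraction_positive",
]


@dataclasses.dataclass
class GateSpec:
    """Markers with per-marker strict positivity thresholds (AND-combined)."""

    markers: list
    thresholds: list | float = 0.0

    def __post_init__(self):
        if np.isscalar(self.thresholds):
            self.thresholds = [float(self.thresholds)] * len(self.markers)
        self.thresholds = [float(t) for t in self.thresholds]
        if len(self.thresholds) != len(self.markers):
            raise ValueError("one threshold per marker required")
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be >= 0")


@dataclasses.dataclass
class GateResult:
    positive: np.ndarray  # boolean per cell
    cell_ids: np.ndarray
    spec: GateSpec

    @property
    def fraction(self) -> float:
        return float(self.positive.mean())

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())


def normalize_numi(m: UmiMatrix) -> pd.DataFrame:
    """Median-library-size normalized counts (cells x genes DataFrame).

    ``numi = count * median(cell totals) / cell total``; zeros stay zero.
    """
    totals = m.cell_totals().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cells present; apply QC first")
    med = np.median(totals)
    numi = m.counts * (med / totals)[:, None]
    return pd.DataFrame(numi, index=m.cell_ids, columns=m.gene_symbols)


def gate_multi(numi: pd.DataFrame, spec: GateSpec) -> GateResult:
    """AND-combined marker gate: positive iff strictly above every threshold.

    Marker lookup is case-insensitive; a missing or ambiguous symbol raises
    with the offending name.
    """
    lower = [str(c).lower() for c in numi.columns]
    positive = np.ones(len(numi), dtype=bool)
    for marker, thr in zip(spec.markers, spec.thresholds):
        hits = [i for i, c in enumerate(lower) if c == marker.lower()]
        if not hits:
            raise KeyError(f"marker not found in matrix: {marker!r}")
        if len(hits) > 1:
            raise KeyError(f"marker symbol ambiguous: {marker!r}")
        positive &= numi.iloc[:, hits[0]].to_numpy() > thr
    return GateResult(
        positive=positive,
        cell_ids=numi.index.to_numpy(dtype=object),
        spec=spec,
    )


def enrichment_by_cluster(gate: GateResult, labels) -> pd.DataFrame:
    """Fraction of gated cells within each cluster, ranked descending.

    Columns: cluster, n_cells, n_positive, fraction.
    """
    labels = np.asarray(labels)
    if len(labels) != len(gate.positive):
        raise ValueError("labels and gate are misaligned")
    rows = []
    for c in np.unique(labels):
        mask = labels == c
        rows.append(
            (c, int(mask.sum()), int(gate.positive[mask].sum()),
             float(gate.positive[mask].mean()))
        )
    table = pd.DataFrame(
        rows, columns=["cluster", "n_cells", "n_positive", "fraction"]
    )
    return table.sort_values("fraction", ascending=False).reset_index(drop=True)


def detect_hybrid_bins(t: PseudotimeAssignment | np.ndarray, lineages,
                       n_bins: int = 10, balance_min: float = 0.4
                       ) -> pd.DataFrame:
    """Flag pseudotime bins where two lineages are near-equally mixed.

    A bin is hybrid iff its minority-lineage fraction >= balance_min
    ("almost equal mixing" at the default 0.4).  Exactly two lineage labels
    are required; flags are symmetric in the two labels.
    """
    lineages = np.asarray(lineages)
    uniq = sorted(set(lineages))
    if len(uniq) != 2:
        raise ValueError(
            f"exactly 2 lineage labels required, got {len(uniq)}: {uniq}"
        )
    comp = bin_composition(lineages, t, n_bins=n_bins)
    fracs = comp[[str(u) for u in uniq]].to_numpy()
    minority = np.nanmin(fracs, axis=1)
    comp = comp.copy()
    comp["minority_fraction"] = minority
    comp["hybrid"] = (minority >= balance_min) & (comp["n_cells"] > 0)
    return comp


def fraction_positive(n_pos: int, n_total: int):
    """Percentage of positive cells; returns ``(raw percent, rounded int)``."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_pos <= n_total:
        raise ValueError("need 0 <= n_pos <= n_total")
    pct = 100.0 * n_pos / n_total
    return pct, int(round(pct))
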
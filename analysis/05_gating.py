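#!/usr/bin/env python
"""Multi-marker gating of hybrid cells and count-based quantification.

Gates quadruple-positive cells (nUMI > 0 on two markers from each lineage)
in a simulation with 11% planted hybrid cells, ranks per-cluster enrichment,
flags near-equally mixed pseudotime bins, and reproduces the printed
single-cell-western worked example (77 of 1293 cells ~ 6%).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from scwound.gating import (GateSpec, detect_hybrid_bins,
                            enrichment_by_cluster, fraction_positive,
                            gate_multi, normalize_numi)
from scwound.io import write_results
from scwound.simulate import SimConfig, simulate_conversion, simulate_counts

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(n_cells=5000, n_genes=300, n_types=2, frac_hybrid=0.11,
                    seed=SEED)
    m, meta, truth = simulate_counts(cfg)
    numi = normalize_numi(m)
    mk = truth.extras["marker_symbols_by_type"]
    spec = GateSpec(markers=mk["type0"][:2] + mk["type1"][:2], thresholds=0)
    res = gate_multi(numi, spec)
    print(f"quadruple-positive gate ({', '.join(spec.markers)}): "
          f"{res.n_positive}/{m.n_cells} cells = {100*res.fraction:.1f}% "
          f"(planted 11.0%)")

    labels = np.where(meta["is_hybrid"], "hybrid", meta["cell_type"])
    enr = enrichment_by_cluster(res, labels)
    write_results(enr, OUT / "gate_enrichment.tsv")
    print(f"most enriched group: {enr.loc[0, 'cluster']} "
          f"({100*enr.loc[0, 'fraction']:.1f}% positive)")

    _, _, conv_meta, conv_truth = simulate_conversion(seed=SEED)
    comp = detect_hybrid_bins(conv_truth.pseudotime, conv_truth.lineage,
                              n_bins=10)
    write_results(comp.reset_index(), OUT / "hybrid_bins.tsv")
    flagged = list(comp.index[comp["hybrid"]])
    print(f"hybrid pseudotime bins (minority fraction >= 0.4): {flagged}")

    raw, rounded = fraction_positive(77, 1293)
    print(f"single-cell western worked example: 77/1293 = {raw:.2f}% "
          f"~ {rounded}% double-positive")


if __name__ == "__main__":
    main()
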
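#!/usr/bin/env python
"""Generate the study's synthetic datasets and write them to disk.

Produces a droplet-style UMI bundle with planted pseudotime-dependent genes
and hybrid cells, the QC boundary fixture, and a spliced/unspliced pair from
the two-lineage conversion kinetics.  Everything downstream (02-06) reads
its inputs from the library directly, so this script exists to exercise and
document the on-disk formats.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from scwound.io import write_mtx_bundle, write_results
from scwound.simulate import SimConfig, make_qc_fixture, simulate_conversion, \
    simulate_counts

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)

    cfg = SimConfig(n_cells=2000, n_genes=400, n_types=2, frac_dep_genes=0.25,
                    dep_amplitude=2.0, frac_hybrid=0.11, seed=SEED)
    m, meta, truth = simulate_counts(cfg)
    write_mtx_bundle(m, OUT / "sim_droplet")
    write_results(meta, OUT / "sim_droplet_meta.tsv")
    write_results(truth.dep_params, OUT / "sim_droplet_dep_genes.tsv")
    print(f"droplet simulation: {m.n_cells} cells x {m.n_genes} genes, "
          f"{len(truth.dep_gene_ids)} planted pseudotime-dependent genes, "
          f"{len(truth.hybrid_cell_ids)} hybrid cells "
          f"-> {OUT/'sim_droplet'}")

    fx, fx_truth = make_qc_fixture(SEED)
    rows = [
        {"cell": c, "droplet_fail": fx_truth.qc_fail["droplet"].get(c, ""),
         "fulllength_fail": fx_truth.qc_fail["fulllength"].get(c, "")}
        for c in fx.cell_ids
    ]
    write_results(pd.DataFrame(rows), OUT / "qc_fixture_truth.tsv")
    print(f"QC fixture: {fx.n_cells} cells, "
          f"{len(fx_truth.qc_fail['droplet'])} droplet failures, "
          f"{len(fx_truth.qc_fail['fulllength'])} full-length failures")

    sm, um, conv_meta, conv_truth = simulate_conversion(seed=SEED)
    write_mtx_bundle(sm, OUT / "sim_conversion_spliced")
    write_mtx_bundle(um, OUT / "sim_conversion_unspliced")
    write_results(conv_meta, OUT / "sim_conversion_meta.tsv")
    n_a = (conv_truth.lineage == "myeloid").sum()
    print(f"conversion simulation: {sm.n_cells} cells "
          f"({n_a} myeloid, {sm.n_cells - n_a} fibroblast), "
          f"{sm.n_genes} kinetic genes")


if __name__ == "__main__":
    main()
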
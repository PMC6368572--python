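# scwound

Single-cell RNA-seq analysis of wound fibroblast heterogeneity: the
computational pipeline used to ask whether healing skin wounds contain
hybrid myeloid-derived myofibroblasts, rebuilt as a tested Python library
with seeded synthetic data so every stage is verifiable by parameter
recovery.

The pipeline covers:

* **QC + normalization** — droplet rules (keep cells with < 8000 UMI,
  < 2500 genes, ≤ 8% mitochondrial counts) and full-length rules (remove
  cells with > 11,000 genes or > 15% mito, then genes in < 3 surviving
  cells); library-size log1p normalization; HVG selection by binned
  dispersion (mean > 0.01, bin-normalized variance/mean > 1.0).
* **Clustering & annotation** — PCA on HVGs, shared-nearest-neighbor graph,
  seeded modularity clustering at a resolution parameter; one-vs-rest
  bimodal likelihood-ratio marker test (p < 0.01, logFC > 0.25);
  correlation-distance average-linkage cluster dendrograms; cell-cycle
  scoring against packaged core sets of 43 G1/S and 54 G2/M genes.
* **Pseudotime-dependent genes** — the central statistic: pseudotime split
  into 10 equal bins, per-bin Tukey trimean of each gene, natural cubic
  regression spline smoothing, and a permutation null for the standard
  deviation of the smoothed profile. A gene is called iff SD > 0.5 and
  Bonferroni-corrected permutation p < 0.01; significant genes are grouped
  into temporal clusters pC1..pCk ordered by peak time.
* **Marker gating** — normalized-UMI thresholds combined by AND (e.g.
  quadruple-positive Lyz2+/Acta2+/Tagln+/Col12a1+ cells), per-cluster
  enrichment, and detection of pseudotime bins where two lineages mix
  near-equally.
* **RNA velocity** — gene-relative steady-state model: kNN-pooled spliced/
  unspliced counts (k = 100, 40 PCs), per-gene γ from extreme-quantile
  regression through the origin, residual velocity v = u − γs, and
  correlation-kernel projection onto a 2D embedding (n_sight = 3500).
* **Synthetic data** — negative-binomial UMI counts over marker-defined
  populations with a latent pseudotime, planted dependent genes of known
  shape and amplitude, planted hybrid cells, mitochondrial content, and
  spliced/unspliced pairs from exact two-stage transcription kinetics.

See `docs/methods.md` for models, assumptions, parameter defaults, and
limitations.

## Worked example

Detecting planted pseudotime-dependent genes and gating planted hybrid
cells:

```python
from scwound.simulate import SimConfig, simulate_counts
from scwound.qc import normalize_log
from scwound.pseudotime import PtDepParams, PseudotimeAssignment, \
    test_pseudotime_dependence, cluster_dep_genes
from scwound.gating import GateSpec, gate_multi, normalize_numi

cfg = SimConfig(n_cells=2000, n_genes=400, n_types=2, frac_dep_genes=0.25,
                dep_amplitude=2.0, frac_hybrid=0.11, seed=1)
m, meta, truth = simulate_counts(cfg)

e = normalize_log(m)
t = PseudotimeAssignment(truth.pseudotime, source="truth")
res = test_pseudotime_dependence(e, t, PtDepParams(n_perms=200, seed=1))
print(res.table["significant"].sum(), "of", len(res.table), "genes significant")

mk = truth.extras["marker_symbols_by_type"]
gate = gate_multi(normalize_numi(m),
                  GateSpec(markers=mk["type0"][:2] + mk["type1"][:2]))
print(f"quadruple-positive fraction: {100 * gate.fraction:.1f}%")
```

prints

```
95 of 400 genes significant
quadruple-positive fraction: 11.1%
```

— 95 of the 100 planted genes pass the SD > 0.5 / Bonferroni p < 0.01 gate
with zero false positives among the 300 null genes, and the four-marker
gate recovers the planted 11% hybrid fraction.

The numbered scripts under `analysis/` run the full narrative —
simulation, QC, clustering/markers/cell cycle, pseudotime genes, gating,
velocity — and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/04_pseudotime_genes.py   # etc.
```

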
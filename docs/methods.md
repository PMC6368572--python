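# Methods

`scwound` re-implements, as a tested library plus narrative analysis
scripts, the computational workflow used to dissect fibroblast heterogeneity
in healing mouse skin wounds by single-cell RNA-seq: droplet and full-length
quality control, normalization and highly variable gene (HVG) selection,
graph clustering with marker ranking and cluster relatedness, cell-cycle
scoring, a permutation test for pseudotime-dependent gene expression,
multi-marker gating of hybrid myeloid/fibroblast cells, and a simplified
gene-relative RNA-velocity estimator. Because the original droplet and
full-length datasets are external, every stage is validated by parameter
recovery on a synthetic-data generator that emulates the statistical
structure the analysis assumes.

## Quality control and normalization

Two dialects, matching the two capture chemistries:

* **droplet** (3'-end counting): a cell is kept iff total UMI < 8000
  (strict), detected genes < 2500 (strict), and mitochondrial fraction
  <= 8% (inclusive). Genes are untouched.
* **full-length** (microfluidic): cells with detected genes > 11,000 or
  mitochondrial count fraction > 15% are removed (strict-exceed); genes
  expressed in fewer than 3 of the *surviving* cells are then removed, so a
  gene can be lost because its supporting cells failed QC.

Boundary strictness follows the protocol wording literally and is pinned by
tests (a cell at exactly 8000 UMI is removed; one at exactly 8% mito is
kept; a gene in exactly 3 surviving cells is kept). Mitochondrial genes are
recognized by the mouse "mt-" symbol prefix (case-insensitive,
configurable); no explicit mito gene list is assumed.

One caveat the test suite documents: re-applying full-length QC to its own
output is a no-op on typical data, but a cell sitting exactly on the mito
boundary can flip on re-application, because removing under-supported genes
changes its count composition. QC metrics are defined on the matrix as
presented.

Normalization is library-size scaling to 10,000 counts per cell followed by
log1p. HVG selection computes per-gene mean and dispersion
(variance / mean) on the normalized *pre-log* counts — variance/mean is a
count-scale statistic — ranks genes into 20 equal-count mean bins (ties
broken by gene id), and divides each gene's dispersion by its bin's median.
A gene is selected iff mean > 0.01 and bin-normalized dispersion > 1.0,
both strict. Applying the dispersion cutoff to the bin-normalized rather
than raw dispersion is a deliberate reading — the binning otherwise plays
no role — and the raw-dispersion variant is available via
`HvgParams(use_bin_normalized=False)`.

## Clustering, markers, relatedness, cell cycle

PCA runs on the HVGs after per-gene centering and unit scaling; components
are ordered by explained variance and signed so the largest-magnitude
loading is positive, making embeddings reproducible. Clustering builds a
k-nearest-neighbor graph (Euclidean in PC space, k = 30 by default),
weights edges by the Jaccard overlap of neighbor sets (shared nearest
neighbors), and optimizes resolution-parameterized modularity with a seeded
Leiden optimizer (`leidenalg`, RB-configuration objective) — the same
modularity family as the Louvain procedure used in standard droplet
workflows, with better optima and explicit seeding. Labels are renumbered
1..K by decreasing cluster size. Defaults mirror the droplet workflow: 40
PCs / resolution 0.45 at the top level, 35 PCs / resolution 0.6 for
subclustering; both are plain parameters.

Markers use a one-vs-rest bimodal likelihood-ratio test: expression is a
point mass at zero plus a Gaussian on positive log-expression, each group
gets free (pi, mu, sigma), and 2(ll_in + ll_out − ll_pooled) is referred to
chi-squared with 3 df. MLEs are closed-form (positive-part mean/SD, a 1e-3
SD floor guards degenerate groups). A gene is a marker iff p < 0.01 and
log fold change (on ln(mean expm1 + 1) scale) > 0.25. A Wilcoxon rank-sum
fallback with the same table schema is provided.

Cluster relatedness averages expression per cluster over the HVGs and runs
average-linkage agglomeration on 1 − Pearson r; the dendrogram is exported
as Newick. Cross-dataset comparison correlates two cluster-signature tables
over their shared genes (error below 10 shared genes) and reports the
best-match cluster per row.

Cell-cycle scoring uses the packaged core sets of 43 G1/S and 54 G2/M mouse
symbols (user-replaceable). Each score is mean(set) − mean(controls), with
controls drawn per set gene from the same average-expression bin (25 bins,
100 seeded draws with replacement). A cell is G1 unless one score is
strictly positive and wins. Control binning protects against depth
artifacts, but when a large majority of cells over-express one set the
controls are drawn largely from that same set and scores compress toward
zero; planted-fraction recovery is tested at realistic phase mixtures.

## Pseudotime-dependent genes

The central statistic. Pseudotime (taken from an external tool, from
simulation truth, or from the principal-curve-style fallback ordering) is
rescaled to [0, 1] and divided into 10 equal-width bins (half-open, last
bin closed). Each gene's per-bin expression is the Tukey trimean
(Q1 + 2·Q2 + Q3)/4 of its log-normalized values, with quartiles by linear
interpolation; empty bins are imputed by linear interpolation from the
nearest non-empty bins and flagged. The binned profile is smoothed by a
natural cubic regression spline (5 df over 10 bins: knots at evenly spaced
quantiles of the bin centers; small enough to smooth, enough curvature for
unimodal bumps), and the statistic is the population SD (denominator
n_bins) of the fitted values.

Significance comes from permutation: cells are randomly reassigned to
pseudotime positions and the binned-trimean → spline → SD pipeline is
recomputed, 1000 times by default (200 in the desk-scale analyses here).
One seeded permutation matrix is shared across genes, which makes results
deterministic and costs O(P) binned summaries instead of O(P·G). The
p-value is the plain exceedance fraction (#permuted SD >= observed)/P —
deliberately without the add-one correction, since with add-one the
smallest attainable p is 1/(P+1) and a Bonferroni correction across
hundreds of genes could never reach alpha = 0.01 at P = 1000; the test
warns when the gene count makes anything but p = 0 insufficient. A gene is
pseudotime-dependent iff SD > 0.5 and Bonferroni-corrected p < 0.01. An
optional flag rescales each smoothed profile to [0, 1] before the SD
(off by default).

Because the SD gate works in absolute log-expression units, family-wise
error control in practice rests on both gates: under the null the
permutation p-value is only super-uniform (P(p <= q) <= q + 1/P), but null
smoothed profiles have SDs far below 0.5 at realistic bin occupancies.
Both properties are verified by simulation.

Significant genes are grouped into temporal clusters: smoothed profiles are
z-scored, clustered hierarchically (1 − Pearson r, average linkage), the
tree is cut at k (default 5, a parameter — no principled k is implied), and
clusters are renamed pC1..pCk by the pseudotime position of their mean
profile's peak, earliest first.

## Marker gating and hybrid bins

nUMI normalization rescales each cell to the median library size (the
exact recipe behind "normalized UMI" is not pinned down by the source
workflow; median scaling is the assumption, documented here). Gates are
AND-combinations of per-marker strict thresholds — 0 for selection gates
("any expression"), 2 for stringent display gates. Gating at threshold 0 is
invariant to the normalization since zeros are preserved. Per-cluster
enrichment ranks the fraction of gated cells per cluster. Hybrid
pseudotime bins are those where the minority of two lineages holds >= 0.4
of the cells ("almost equal mixing", configurable). Count-based
quantification (`fraction_positive`) reports raw and integer-rounded
percentages; 77 of 1293 gives 5.96% ~ 6%.

## RNA velocity

The estimator is the steady-state gene-relative family: spliced (s) and
unspliced (u) counts are pooled by *summing* over each cell's 100 nearest
neighbors (self included) in 40-PC space — sums, not means, so the ratio
fit is scale-free. Per gene, gamma is fit by regression through the origin
of u on s restricted to cells in the top and bottom 2% of pooled s (where
steady state is the best approximation); genes without at least 10 cells
carrying both signals are dropped, and u ≡ 0 yields gamma = 0 with a
degenerate flag. Velocity is the residual v = u − gamma·s: positive during
induction, negative during repression. This extreme-quantile fit replaces
the full fitting machinery of the reference velocity tool; the exact
variant those defaults imply is not specified, so the quantile and kernel
constants here are documented and configurable.

Projection onto a 2D embedding uses the correlation-kernel transition
scheme: each cell's velocity vector is Pearson-correlated (over genes) with
the expression displacement to each of its n_sight = 3500 nearest embedding
neighbors (capped at n−1 for desk-scale simulations), weights are
exp(corr/0.05) normalized, and the arrow is the weighted mean unit
displacement minus the uniform-weight baseline — so a zero-velocity cell
gets a zero arrow, and arrows are invariant to embedding translation. A
Gaussian-kernel grid average (30 × 30, bandwidth 1.5 grid spacings, with a
reported mass per grid point for masking sparse regions) gives the field.

## The synthetic-data generator

`simulate_counts` draws, per cell, a Gamma library size (shape 20 around
5000 UMI) and, per gene, gamma-Poisson (negative binomial) counts with
Var = mu + mu²·disp (disp 0.1). Per-gene relative means are renormalized
per cell so expected totals match the library size, keeping QC thresholds
meaningful. Populations get marker programs: ~10 UMI expected for own-type
markers (strong lineage markers such as collagens are highly expressed) and
near-silence (0.002 relative units, about 3% detection) off-type — marker
specificity is what makes threshold gating a meaningful readout of planted
hybrids. Hybrid cells mix the *mean programs* of two lineages with a
Beta(2,2) weight: transcriptional intermediates, not doublets.
Mitochondrial-flagged genes are scaled to carry a fixed expected share
(default 5%) of each cell's counts.

Pseudotime is Uniform(0,1). Planted dependent genes follow
log-mean = baseline + amplitude · (f(t) − mean f), with f logistic, bump,
or linear; inflections are drawn Uniform(0.2, 0.8) to keep dynamics inside
the observed range. Centering f by its time-average is deliberate: with
many co-directional planted genes, un-centered dynamics inflate cell totals
along pseudotime and per-cell renormalization would divide part of the
planted amplitude back out of every gene; centering keeps the library
composition flat so planted genes carry their stated amplitude in the
normalized expression the test actually sees. No quantitative effect-size
distribution is implied by the source workflow; amplitude 2 (log scale) is
the testability default.

`simulate_spliced_unspliced` evaluates the exact solution of
du/dt = alpha(t) − beta·u, ds/dt = beta·u − gamma·s with step alpha
(induced genes switch on, repressed genes switch off at staggered times)
at each cell's pseudotime and samples Poisson counts — Poisson, not NB,
because the velocity estimator is first-moment based. At steady state
u/s = gamma/beta, which is what the gamma fit recovers.
`simulate_conversion` layers a two-lineage identity on one progression:
50/50 mixing across the planted overlap window t in [0.4, 0.6] (the middle
two of ten bins) with narrow ramps outside, so hybrid-bin detection has an
unambiguous truth; staggered kinetics keep some genes out of equilibrium at
every t, making the planted flow direction recoverable. `make_qc_fixture`
constructs cells sitting exactly on every QC boundary with
independently-computed expected labels. `simulate_two_waves` plants two
groups of bump-shaped genes peaking at t = 0.3 and 0.7 (width 0.15,
amplitude 2.5) for temporal-cluster recovery.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: ambient RNA, doublets, batch effects, bursty
transcription, gene-gene correlation beyond the planted programs, and
realistic gene-count scales (hundreds of genes, not tens of thousands).
Recovery results certify the statistical machinery, not robustness to those
artifacts.

## Problem sizes and numerical choices

Desk-scale defaults keep every analysis under a few minutes on one core:
2000 cells × 200–400 genes for the permutation analyses (200 permutations),
5000 cells for gating, 1200 cells for clustering recovery, 1500 cells × 120
genes for velocity. Tolerances: primitive operations (trimean, spline fit,
HVG rule, average linkage, Pearson r) match independent brute-force
recomputation to 1e-9; recovery thresholds (power >= 90%, purity >= 95%,
gate within 2 percentage points, ARI >= 0.9) are the planted-design
margins. Ties in quantiles use linear interpolation throughout (numpy
default). Degenerate inputs error loudly: constant pseudotime, zero-total
cells, constant cluster signatures, missing or ambiguous marker symbols.

## Out of scope

Read alignment and quantification, BAM-level spliced/unspliced annotation,
quantile normalization and batch correction for the full-length data,
graph-embedding trajectory inference (pseudotime is consumed, with a
principal-curve fallback as plumbing), t-SNE internals (any 2D embedding is
accepted), PC-significance testing (PC counts are parameters), and
likelihood-based dynamical velocity models.
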
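"""Embedding, graph clustering, marker ranking, cluster relatedness,
cell-cycle scoring, and cross-dataset signature correlation.

Clustering follows the droplet workflow: PCA on highly variable genes
(centered, unit-scaled), a shared-nearest-neighbor graph with Jaccard edge
weights in PC space, and resolution-parameterized modularity optimization.
Markers use a bimodal likelihood-ratio test: expression is modeled as a point
mass at zero plus a Gaussian on positive log-expression, and the one-vs-rest
statistic compares free per-group parameters against a pooled fit.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2
from sklearn.neighbors import NearestNeighbors

from .qc import ExprMatrix

__all__ = [
    "ClusterParams",
    "CycleGeneSets",
    "Embedding",
    "run_pca",
    "cluster_graph",
    "rank_markers_lrt",
    "rank_markers_ranksum",
    "cluster_relatedness",
    "linkage_to_newick",
    "score_cell_cycle",
    "cross_correlate_signatures",
    "load_mouse_cycle_genes",
]


@dataclasses.dataclass
class ClusterParams:
    n_pcs: int = 40
    knn_k: int = 30
    resolution: float = 0.45
    marker_min_logfc: float = 0.25
    marker_max_p: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclasses.dataclass
class CycleGeneSets:
    g1s_genes: list
    g2m_genes: list
    n_ctrl_bins: int = 25
    n_ctrl_per_gene: int = 100

    def __post_init__(self):
        overlap = set(self.g1s_genes) & set(self.g2m_genes)
        if overlap:
            raise ValueError(f"cycle gene sets overlap: {sorted(overlap)}")


def load_mouse_cycle_genes() -> CycleGeneSets:
    """Packaged core cell-cycle sets: 43 G1/S and 54 G2/M mouse symbols."""
    text = (
        importlib.resources.files("scwound")
        .joinpath("data/cycle_genes_mouse.txt")
        .read_text()
    )
    g1s, g2m = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        phase, gene = line.split("\t")
        (g1s if phase == "G1/S" else g2m).append(gene)
    return CycleGeneSets(g1s_genes=g1s, g2m_genes=g2m)


@dataclasses.dataclass
class Embedding:
    """PC coordinates (cells x n_pcs) plus decomposition metadata."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # genes x n_pcs
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_pcs(self) -> int:
        return self.coords.shape[1]


def run_pca(e: ExprMatrix, genes, n_pcs: int) -> Embedding:
    """PCA on the given genes after per-gene centering and unit scaling.

    Constant genes are dropped with a warning.  Components are ordered by
    decreasing explained variance and signed so each component's
    largest-magnitude loading is positive, making the embedding deterministic.
    """
    gene_ids = np.asarray(list(genes), dtype=object)
    id_to_col = {g: i for i, g in enumerate(e.gene_ids)}
    missing = [g for g in gene_ids if g not in id_to_col]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}...")
    cols = np.array([id_to_col[g] for g in gene_ids])
    X = e.values[:, cols].astype(float)

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant genes before PCA",
            stacklevel=2,
        )
        X, sd, gene_ids = X[:, keep], sd[keep], gene_ids[keep]
    if n_pcs > min(X.shape):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells, genes)={min(X.shape)}"
        )
    Xs = (X - X.mean(axis=0)) / sd

    # full SVD keeps the decomposition deterministic
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * S
    total_var = (Xs ** 2).sum()
    return Embedding(
        coords=coords,
        explained_variance_ratio=S ** 2 / total_var,
        loadings=Vt.T,
        gene_ids=gene_ids,
        cell_ids=e.cell_ids.copy(),
    )


def _snn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    """kNN (Euclidean) -> shared-nearest-neighbor graph with Jaccard weights."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self at distance 0
    neighbor_sets = [set(row) for row in idx]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                edges.append(key)
                weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_graph(emb: Embedding, p: ClusterParams) -> np.ndarray:
    """Modularity community detection on the SNN graph at the given resolution.

    Returns integer labels 1..K ordered by decreasing cluster size;
    deterministic for a fixed seed.
    """
    n = emb.n_cells
    if n < p.knn_k + 1:
        raise ValueError(f"need more than knn_k={p.knn_k} cells, have {n}")
    g = _snn_graph(emb.coords, p.knn_k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=p.resolution,
        seed=p.seed,
        n_iterations=5,
    )
    raw = np.asarray(part.membership)
    # relabel 1..K by decreasing size, ties by first appearance
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: i + 1 for i, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


# ---------------------------------------------------------------------------
# bimodal likelihood-ratio marker test
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-3


def _bimod_loglik(x: np.ndarray) -> float:
    """Max log-likelihood of the zero / positive-Gaussian mixture for x."""
    n = len(x)
    pos = x[x > 0]
    n1 = len(pos)
    n0 = n - n1
    ll = 0.0
    if 0 < n1 < n:
        pi = n1 / n
        ll += n0 * np.log(1 - pi) + n1 * np.log(pi)
    if n1 > 0:
        mu = pos.mean()
        sigma = max(pos.std(ddof=0), _SIGMA_FLOOR)
        ll += (
            -n1 * np.log(sigma)
            - 0.5 * n1 * np.log(2 * np.pi)
            - 0.5 * ((pos - mu) ** 2).sum() / sigma**2
        )
    return ll


def rank_markers_lrt(e: ExprMatrix, labels, p: ClusterParams | None = None
                     ) -> pd.DataFrame:
    """One-vs-rest bimodal LRT marker table.

    Per gene and cluster, the in-group and out-group each get free
    (pi, mu, sigma) parameters; the statistic is
    2 * (ll_in + ll_out - ll_pooled) against chi^2 with 3 degrees of freedom.
    log_fc compares ln(mean(expm1) + 1) between groups.  Rows are flagged as
    markers iff p < marker_max_p and log_fc > marker_min_logfc.
    """
    p = p or ClusterParams()
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    for c in clusters:
        if (labels == c).sum() < 3:
            raise ValueError(f"cluster {c} has fewer than 3 cells")

    rows = []
    X = e.values
    for c in clusters:
        in_mask = labels == c
        Xi, Xo = X[in_mask], X[~in_mask]
        mean_in = np.log(np.expm1(Xi).mean(axis=0) + 1)
        mean_out = np.log(np.expm1(Xo).mean(axis=0) + 1)
        log_fc = mean_in - mean_out
        pct_in = (Xi > 0).mean(axis=0)
        pct_out = (Xo > 0).mean(axis=0)
        for gi in range(e.n_genes):
            xi, xo = Xi[:, gi], Xo[:, gi]
            if not (xi > 0).any() and not (xo > 0).any():
                continue  # all-zero gene: nothing to test
            stat = 2 * (
                _bimod_loglik(xi)
                + _bimod_loglik(xo)
                - _bimod_loglik(np.concatenate([xi, xo]))
            )
            stat = max(stat, 0.0)
            pval = chi2.sf(stat, df=3)
            rows.append(
                (
                    e.gene_ids[gi],
                    c,
                    log_fc[gi],
                    pval,
                    np.nan,
                    pct_in[gi],
                    pct_out[gi],
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "log_fc", "p_value", "p_adj",
                 "pct_in", "pct_out"],
    )
    table["p_adj"] = np.minimum(table["p_value"] * len(table), 1.0)
    table["is_marker"] = (table["p_value"] < p.marker_max_p) & (
        table["log_fc"] > p.marker_min_logfc
    )
    return table.sort_values(["cluster", "p_value", "gene"]).reset_index(
        drop=True
    )


def rank_markers_ranksum(e: ExprMatrix, labels, p: ClusterParams | None = None
                         ) -> pd.DataFrame:
    """Wilcoxon rank-sum fallback with the same table schema as the LRT."""
    from scipy.stats import mannwhitneyu

    p = p or ClusterParams()
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    rows = []
    X = e.values
    for c in clusters:
        in_mask = labels == c
        Xi, Xo = X[in_mask], X[~in_mask]
        mean_in = np.log(np.expm1(Xi).mean(axis=0) + 1)
        mean_out = np.log(np.expm1(Xo).mean(axis=0) + 1)
        for gi in range(e.n_genes):
            xi, xo = Xi[:, gi], Xo[:, gi]
            if not (xi > 0).any() and not (xo > 0).any():
                continue
            pval = mannwhitneyu(xi, xo, alternative="two-sided").pvalue
            rows.append(
                (e.gene_ids[gi], c, mean_in[gi] - mean_out[gi], pval,
                 np.nan, (xi > 0).mean(), (xo > 0).mean())
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "log_fc", "p_value", "p_adj",
                 "pct_in", "pct_out"],
    )
    table["p_adj"] = np.minimum(table["p_value"] * len(table), 1.0)
    table["is_marker"] = (table["p_value"] < p.marker_max_p) & (
        table["log_fc"] > p.marker_min_logfc
    )
    return table.sort_values(["cluster", "p_value", "gene"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# cluster relatedness and cross-dataset correlation
# ---------------------------------------------------------------------------

def cluster_signatures(e: ExprMatrix, labels, genes=None) -> pd.DataFrame:
    """Per-cluster mean expression over the given genes (default: all)."""
    labels = np.asarray(labels)
    if genes is None:
        cols = np.arange(e.n_genes)
        gene_ids = e.gene_ids
    else:
        id_to_col = {g: i for i, g in enumerate(e.gene_ids)}
        cols = np.array([id_to_col[g] for g in genes])
        gene_ids = np.asarray(list(genes), dtype=object)
    sig = {}
    for c in np.unique(labels):
        sig[str(c)] = e.values[labels == c][:, cols].mean(axis=0)
    return pd.DataFrame(sig, index=gene_ids)


def cluster_relatedness(e: ExprMatrix, labels, genes=None):
    """Average-linkage dendrogram of cluster signatures, distance 1 - Pearson r.

    Returns ``(linkage matrix, cluster name list)``; merge heights are
    non-decreasing by construction of average linkage on a metric-free
    dissimilarity.
    """
    sig = cluster_signatures(e, labels, genes=genes)
    names = list(sig.columns)
    if len(names) < 2:
        raise ValueError("need >= 2 clusters")
    mat = sig.to_numpy().T  # clusters x genes
    sds = mat.std(axis=1)
    for name, sd in zip(names, sds):
        if sd == 0:
            raise ValueError(f"cluster {name} has a constant signature")
    corr = np.corrcoef(mat)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, names


def linkage_to_newick(Z: np.ndarray, names) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(names[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


def cross_correlate_signatures(sig_a: pd.DataFrame, sig_b: pd.DataFrame):
    """Pearson correlation between two signature tables on shared genes.

    Both inputs are genes x clusters.  Returns ``(r matrix as DataFrame
    [A clusters x B clusters], best-match Series per A cluster, n shared)``.
    """
    shared = sig_a.index.intersection(sig_b.index)
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} shared genes between signatures (need >= 10)"
        )
    A = sig_a.loc[shared].to_numpy().T
    B = sig_b.loc[shared].to_numpy().T
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.outer(
        np.sqrt((Ac**2).sum(axis=1)), np.sqrt((Bc**2).sum(axis=1))
    )
    r = (Ac @ Bc.T) / denom
    rmat = pd.DataFrame(r, index=sig_a.columns, columns=sig_b.columns)
    best = rmat.idxmax(axis=1)
    return rmat, best, len(shared)


# ---------------------------------------------------------------------------
# cell-cycle scoring
# ---------------------------------------------------------------------------

def score_cell_cycle(e: ExprMatrix, sets: CycleGeneSets | None = None,
                     seed: int = 0):
    """Score each cell for G1/S and G2/M programs and call a phase.

    Each score is mean(set genes) - mean(control genes); controls are drawn,
    per set gene, from the same average-expression bin (n_ctrl_bins bins over
    all genes, n_ctrl_per_gene seeded draws with replacement).  Phase is G1
    when both scores are negative, otherwise whichever score is larger.

    Returns a DataFrame with columns cell, s_score, g2m_score, phase.
    """
    sets = sets or load_mouse_cycle_genes()
    rng = np.random.default_rng(seed)
    sym_to_col = {}
    for i, s in enumerate(e.gene_symbols):
        sym_to_col.setdefault(str(s).lower(), i)

    def _cols(genes, label):
        cols = [sym_to_col[g.lower()] for g in genes if g.lower() in sym_to_col]
        if not cols:
            raise ValueError(f"no {label} genes present in the matrix")
        if len(cols) < 0.5 * len(genes):
            warnings.warn(
                f"only {len(cols)}/{len(genes)} {label} genes present",
                stacklevel=3,
            )
        return np.array(cols)

    g1s_cols = _cols(sets.g1s_genes, "G1/S")
    g2m_cols = _cols(sets.g2m_genes, "G2/M")

    avg = e.values.mean(axis=0)
    ranks = pd.Series(avg).rank(method="first").to_numpy()
    bin_of = np.minimum(
        ((ranks - 1) / len(ranks) * sets.n_ctrl_bins).astype(int),
        sets.n_ctrl_bins - 1,
    )
    bin_members = {b: np.where(bin_of == b)[0] for b in range(sets.n_ctrl_bins)}

    def _score(cols):
        ctrl_cols = []
        for c in cols:
            pool = bin_members[bin_of[c]]
            ctrl_cols.append(rng.choice(pool, size=sets.n_ctrl_per_gene,
                                        replace=True))
        ctrl_cols = np.concatenate(ctrl_cols)
        return e.values[:, cols].mean(axis=1) - e.values[:, ctrl_cols].mean(axis=1)

    s_score = _score(g1s_cols)
    g2m_score = _score(g2m_cols)
    # G1 unless one program scores strictly positive and wins
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {
            "cell": e.cell_ids,
            "s_score": s_score,
            "g2m_score": g2m_score,
            "phase": phase,
        }
    )
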
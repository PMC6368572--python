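"""Pseudotime-dependent gene detection.

The statistic: pseudotime is divided into 10 equal-width bins; each gene's
per-bin expression is summarized by the Tukey trimean (Q1 + 2*Q2 + Q3)/4 of
its log-normalized values; the binned profile is smoothed with a natural
cubic regression spline; the standard deviation of the smoothed profile
measures how much the gene moves along pseudotime.  Significance comes from
a permutation null — cells are randomly reassigned to pseudotime positions
(one shared, seeded permutation set across genes) and the SD recomputed —
with a Bonferroni correction over the genes tested.  A gene is called
pseudotime-dependent iff SD > 0.5 and Bonferroni-corrected p < 0.01.

The permutation p-value is the plain count fraction (#permuted SD >= observed)
/ n_perms, without an add-one correction: with add-one the smallest possible
p is 1/(P+1), and a Bonferroni correction across hundreds of genes could never
reach alpha = 0.01 at P = 1000 permutations.  Allowing p = 0 is what makes the
Bonferroni gate attainable; `test_pseudotime_dependence` warns when the gene
count makes anything but p = 0 insufficient.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .qc import ExprMatrix

__all__ = [
    "PtDepParams",
    "PseudotimeAssignment",
    "GeneTestResults",
    "estimate_pseudotime_fallback",
    "bin_pseudotime",
    "trimean",
    "trimean_profile",
    "natural_spline_basis",
    "spline_hat_matrix",
    "smooth_profile",
    "test_pseudotime_dependence",
    "cluster_dep_genes",
    "bin_composition",
]


@dataclasses.dataclass
class PtDepParams:
    n_bins: int = 10
    n_perms: int = 1000
    sd_threshold: float = 0.5
    alpha: float = 0.01
    spline_df: int = 5
    n_gene_clusters: int = 5
    min_expr_frac: float = 0.01
    #: rescale each smoothed profile to [0, 1] before the SD statistic
    rescale_before_sd: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 3:
            raise ValueError("n_bins must be >= 3")
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")
        if not 2 <= self.spline_df <= self.n_bins:
            raise ValueError("need 2 <= spline_df <= n_bins")


@dataclasses.dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime, rescaled to [0, 1], with a provenance tag."""

    values: np.ndarray
    source: str = "external"  # external | fallback | truth

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("pseudotime contains non-finite values")
        span = v.max() - v.min()
        if span > 0:
            v = (v - v.min()) / span
        self.values = v


def estimate_pseudotime_fallback(emb, n_curve_points: int = 100,
                                 n_iter: int = 8, reverse: bool = False,
                                 ) -> PseudotimeAssignment:
    """Principal-curve-style 1D ordering of cells in PC space.

    Starts from the PC1 ordering and alternates between smoothing each
    coordinate along the current ordering (moving-average over the ordered
    cells) and re-projecting cells onto the resulting polyline.  Arc-length
    position is rescaled to [0, 1].  This is plumbing: a stand-in ordering
    for workflows that normally consume an externally inferred trajectory.
    """
    coords = emb.coords if hasattr(emb, "coords") else np.asarray(emb, float)
    n, d = coords.shape
    if n < 10:
        raise ValueError("need >= 10 cells for the fallback ordering")
    if d < 2:
        raise ValueError("need >= 2 embedding dimensions")

    lam = coords[:, 0].copy()
    window = max(5, n // 20)
    kernel = np.ones(window) / window
    for _ in range(n_iter):
        order = np.argsort(lam, kind="stable")
        # smooth each coordinate along the ordering
        smooth = np.empty_like(coords)
        for j in range(d):
            padded = np.pad(coords[order, j], (window // 2, window - 1 - window // 2),
                            mode="edge")
            smooth[:, j] = np.convolve(padded, kernel, mode="valid")
        # resample the smoothed path to a fixed-size polyline
        idx = np.linspace(0, n - 1, n_curve_points).astype(int)
        curve = smooth[idx]
        seg = np.diff(curve, axis=0)
        seg_len = np.sqrt((seg**2).sum(axis=1))
        arc = np.concatenate([[0.0], np.cumsum(seg_len)])
        # project every cell to its nearest curve point
        d2 = ((coords[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        lam = arc[nearest]
    t = lam
    if reverse:
        t = t.max() - t
    return PseudotimeAssignment(values=t, source="fallback")


def bin_pseudotime(t: PseudotimeAssignment | np.ndarray, n_bins: int
                   ) -> np.ndarray:
    """Equal-width bins over [min t, max t]; half-open except the last.

    Returns bin ids 1..n_bins per cell.
    """
    v = t.values if isinstance(t, PseudotimeAssignment) else np.asarray(t, float)
    if len(v) < 1:
        raise ValueError("no cells")
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValueError("all pseudotime values identical; cannot bin")
    width = (hi - lo) / n_bins
    idx = np.minimum(((v - lo) / width).astype(int), n_bins - 1)
    return idx + 1


def bin_centers(t, n_bins: int) -> np.ndarray:
    v = t.values if isinstance(t, PseudotimeAssignment) else np.asarray(t, float)
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    return (edges[:-1] + edges[1:]) / 2


def trimean(x: np.ndarray) -> float:
    """Tukey trimean (Q1 + 2*Q2 + Q3) / 4, quartiles by linear interpolation."""
    q1, q2, q3 = np.quantile(np.asarray(x, float), [0.25, 0.5, 0.75])
    return (q1 + 2 * q2 + q3) / 4


def _binned_trimeans(values: np.ndarray, bins: np.ndarray, n_bins: int
                     ) -> np.ndarray:
    """Trimean per bin for a matrix of cells x genes; NaN for empty bins."""
    G = values.shape[1]
    out = np.full((n_bins, G), np.nan)
    for b in range(1, n_bins + 1):
        mask = bins == b
        if mask.any():
            q = np.quantile(values[mask], [0.25, 0.5, 0.75], axis=0)
            out[b - 1] = (q[0] + 2 * q[1] + q[2]) / 4
    return out  # n_bins x genes


def _interp_empty(profile: np.ndarray, centers: np.ndarray):
    """Fill NaN bins by linear interpolation from the nearest non-empty bins."""
    out = profile.copy()
    nan = np.isnan(out)
    if nan.any():
        out[nan] = np.interp(centers[nan], centers[~nan], out[~nan])
    return out, nan


def trimean_profile(e: ExprMatrix, gene: str, bins: np.ndarray,
                    n_bins: int | None = None):
    """Binned trimean profile of one gene's log-normalized expression.

    Empty bins are imputed by linear interpolation from the nearest non-empty
    neighbors and flagged.  Returns ``(profile, empty_flag)`` arrays of
    length n_bins.
    """
    n_bins = n_bins or int(bins.max())
    col = e.gene_index(gene) if isinstance(gene, str) else int(gene)
    prof = _binned_trimeans(e.values[:, [col]], bins, n_bins)[:, 0]
    centers = np.arange(1, n_bins + 1, dtype=float)
    if np.isnan(prof).all():
        raise ValueError("every bin is empty")
    return _interp_empty(prof, centers)


# ---------------------------------------------------------------------------
# natural cubic regression spline
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis with *df* columns (intercept included).

    Knots: df total (2 boundary + df-2 interior) at evenly spaced quantiles
    of x.  Columns are 1, x, and the df-2 standard natural truncated-power
    terms, which are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2")
    knots = np.quantile(np.unique(x), np.linspace(0, 1, df))
    K = len(knots)

    def d(k):
        num = (np.maximum(x - knots[k], 0) ** 3
               - np.maximum(x - knots[K - 1], 0) ** 3)
        return num / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    if K > 2:
        dK1 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK1)
    return np.column_stack(cols)


def spline_hat_matrix(x: np.ndarray, df: int) -> np.ndarray:
    """Least-squares hat matrix of the natural spline fit at points x."""
    N = natural_spline_basis(x, df)
    return N @ np.linalg.pinv(N)


def smooth_profile(profile: np.ndarray, spline_df: int = 5,
                   x: np.ndarray | None = None) -> np.ndarray:
    """Fitted values of a natural cubic regression spline at the bin centers."""
    profile = np.asarray(profile, dtype=float)
    if not np.isfinite(profile).all():
        raise ValueError("profile contains non-finite values")
    if len(profile) < spline_df:
        raise ValueError("need n_bins >= spline_df")
    if x is None:
        x = np.arange(1, len(profile) + 1, dtype=float)
    return spline_hat_matrix(x, spline_df) @ profile


# ---------------------------------------------------------------------------
# the permutation test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneTestResults:
    """Per-gene pseudotime-dependence results.

    ``table`` has columns gene, sd, pval, padj, significant, cluster
    (cluster is filled by :func:`cluster_dep_genes`); ``trimean_profiles``
    and ``smoothed_profiles`` are genes x n_bins matrices aligned to the
    table rows.
    """

    table: pd.DataFrame
    trimean_profiles: np.ndarray
    smoothed_profiles: np.ndarray
    bin_centers: np.ndarray
    params: PtDepParams

    @property
    def significant_genes(self) -> list:
        return list(self.table.loc[self.table["significant"], "gene"])


def _profile_sds(smoothed: np.ndarray, rescale: bool) -> np.ndarray:
    """Population SD per profile row, optionally after [0, 1] rescaling."""
    if rescale:
        lo = smoothed.min(axis=1, keepdims=True)
        rng = smoothed.max(axis=1, keepdims=True) - lo
        rng[rng == 0] = 1.0
        smoothed = (smoothed - lo) / rng
    return smoothed.std(axis=1, ddof=0)


def test_pseudotime_dependence(e: ExprMatrix, t: PseudotimeAssignment,
                               p: PtDepParams | None = None,
                               genes=None) -> GeneTestResults:
    """Permutation test for pseudotime-dependent expression, all genes at once.

    Genes expressed in fewer than ``min_expr_frac`` of cells are excluded
    before testing (and before the Bonferroni factor is set).  One shared,
    seeded permutation matrix is used for every gene, which makes the test
    deterministic and costs O(n_perms) binned summaries rather than
    O(n_perms * n_genes).
    """
    p = p or PtDepParams()
    tv = t.values
    if len(tv) != e.n_cells:
        raise ValueError("pseudotime and expression matrix are misaligned")

    if genes is None:
        expr_frac = (e.values > 0).mean(axis=0)
        cols = np.where(expr_frac >= p.min_expr_frac)[0]
    else:
        id_to_col = {g: i for i, g in enumerate(e.gene_ids)}
        cols = np.array([id_to_col[g] for g in genes])
    if len(cols) == 0:
        raise ValueError("no genes pass the expression filter")
    G = len(cols)
    if G / p.n_perms >= p.alpha:
        warnings.warn(
            f"{G} genes at {p.n_perms} permutations: Bonferroni-corrected "
            f"significance at alpha={p.alpha} is only reachable at p = 0",
            stacklevel=2,
        )

    bins = bin_pseudotime(t, p.n_bins)
    order = np.argsort(tv, kind="stable")
    X = e.values[order][:, cols]  # cells sorted by pseudotime
    sorted_bins = bins[order]
    centers = np.arange(1, p.n_bins + 1, dtype=float)
    H = spline_hat_matrix(centers, p.spline_df)

    def _sd_and_profiles(values):
        prof = _binned_trimeans(values, sorted_bins, p.n_bins)  # bins x G
        if np.isnan(prof).any():  # empty bins: interpolate per gene
            for g in range(prof.shape[1]):
                prof[:, g], _ = _interp_empty(prof[:, g], centers)
        smoothed = (H @ prof).T  # genes x bins
        return _profile_sds(smoothed, p.rescale_before_sd), prof.T, smoothed

    sd_obs, tri_obs, smooth_obs = _sd_and_profiles(X)

    rng = np.random.default_rng(p.seed)
    exceed = np.zeros(G, dtype=np.int64)
    n = X.shape[0]
    for _ in range(p.n_perms):
        perm = rng.permutation(n)
        sd_perm, _, _ = _sd_and_profiles(X[perm])
        exceed += sd_perm >= sd_obs
    p_perm = exceed / p.n_perms
    p_bonf = np.minimum(p_perm * G, 1.0)
    significant = (sd_obs > p.sd_threshold) & (p_bonf < p.alpha)

    table = pd.DataFrame(
        {
            "gene": e.gene_ids[cols],
            "sd": sd_obs,
            "pval": p_perm,
            "padj": p_bonf,
            "significant": significant,
            "cluster": "",
        }
    )
    return GeneTestResults(
        table=table,
        trimean_profiles=tri_obs,
        smoothed_profiles=smooth_obs,
        bin_centers=bin_centers(t, p.n_bins),
        params=p,
    )


def cluster_dep_genes(results: GeneTestResults,
                      n_gene_clusters: int | None = None) -> pd.Series:
    """Group significant genes into temporal clusters pC1..pCk.

    Profiles are z-scored, clustered hierarchically (1 - Pearson r, average
    linkage) and the tree cut at k; clusters are renamed so the earliest-
    peaking mean profile is pC1.  The labels are also written into
    ``results.table["cluster"]``.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    p = results.params
    k = n_gene_clusters or p.n_gene_clusters
    sig_mask = results.table["significant"].to_numpy()
    n_sig = int(sig_mask.sum())
    if n_sig < k:
        raise ValueError(
            f"only {n_sig} significant genes for {k} requested clusters"
        )
    prof = results.smoothed_profiles[sig_mask]
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (prof - mu) / sd

    dist = pdist(z, metric="correlation")
    Z = linkage(np.clip(dist, 0, None), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order clusters by the pseudotime position of their mean-profile peak
    peaks = {}
    for c in np.unique(raw):
        peaks[c] = np.argmax(z[raw == c].mean(axis=0))
    order = sorted(peaks, key=lambda c: (peaks[c], c))
    rename = {c: f"pC{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series(
        [rename[c] for c in raw],
        index=results.table.index[sig_mask],
        name="cluster",
    )
    results.table.loc[labels.index, "cluster"] = labels
    return labels


def bin_composition(labels, t: PseudotimeAssignment | np.ndarray,
                    n_bins: int = 10) -> pd.DataFrame:
    """Per-bin fraction of cells carrying each label.

    Returns a DataFrame indexed by bin (1..n_bins) with one fraction column
    per label plus an ``n_cells`` column; fractions in each non-empty bin sum
    to 1, empty bins report 0 cells and NaN fractions.
    """
    labels = np.asarray(labels)
    bins = bin_pseudotime(t, n_bins)
    uniq = sorted(set(labels))
    rows = []
    for b in range(1, n_bins + 1):
        mask = bins == b
        n = int(mask.sum())
        if n == 0:
            rows.append([np.nan] * len(uniq) + [0])
        else:
            rows.append([(labels[mask] == u).mean() for u in uniq] + [n])
    return pd.DataFrame(
        rows, index=pd.RangeIndex(1, n_bins + 1, name="bin"),
        columns=[str(u) for u in uniq] + ["n_cells"],
    )
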
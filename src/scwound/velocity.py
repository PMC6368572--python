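"""Simplified gene-relative steady-state RNA velocity.

The model: unspliced abundance u feeds spliced abundance s with degradation
rate gamma; near steady state u = gamma' * s for a per-gene constant gamma'
(the degradation/splicing rate ratio).  Velocity is the residual
v = u - gamma' * s: positive during transcriptional induction, negative
during repression.  gamma' is fit by regression through the origin on cells
in the extreme quantiles of pooled spliced expression, where steady state is
the best approximation.  Counts are pooled over k nearest neighbors in PC
space (self included, pooling by sum) before fitting.

Projection onto a 2D embedding follows the correlation-kernel transition
scheme: each cell's velocity vector is correlated with the expression
displacement toward each of its n_sight nearest embedding neighbors;
exponential-kernel weights on those correlations give a transition
distribution, and the arrow is the weighted mean unit displacement minus the
uniform-weight baseline (so a zero-velocity cell gets a zero arrow).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "VelocityParams",
    "GridField",
    "pool_knn",
    "fit_gamma",
    "compute_velocity",
    "project_velocity",
    "grid_field",
    "direction_of_progression",
]


@dataclasses.dataclass
class VelocityParams:
    knn_k: int = 100
    n_pcs: int = 40
    extreme_quantile: float = 0.02
    min_cells: int = 10
    n_sight: int = 3500
    corr_scale: float = 0.05
    grid_n: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.extreme_quantile < 0.5:
            raise ValueError("extreme_quantile must be in (0, 0.5)")


@dataclasses.dataclass
class GridField:
    """Velocity arrows aggregated on a regular lattice over the embedding."""

    points: np.ndarray  # grid_n^2 x 2
    arrows: np.ndarray  # grid_n^2 x 2
    mass: np.ndarray    # kernel-weighted cell mass per grid point


def _as_array(m):
    return m.counts if hasattr(m, "counts") else np.asarray(m, dtype=float)


def pool_knn(spliced, unspliced, emb, p: VelocityParams | None = None):
    """Sum counts over each cell's k nearest neighbors (self included).

    Distances are Euclidean in the embedding (PC coordinates).  k = 0 returns
    the raw matrices.
    """
    p = p or VelocityParams()
    S = _as_array(spliced).astype(float)
    U = _as_array(unspliced).astype(float)
    if S.shape != U.shape:
        raise ValueError("spliced and unspliced matrices differ in shape")
    coords = emb.coords if hasattr(emb, "coords") else np.asarray(emb, float)
    n = S.shape[0]
    if p.knn_k >= n:
        raise ValueError(f"knn_k={p.knn_k} must be < n_cells={n}")
    if p.knn_k == 0:
        return S.copy(), U.copy()
    nn = NearestNeighbors(n_neighbors=p.knn_k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    # guarantee self-inclusion (ties at distance 0 can displace it)
    for i in range(n):
        if i not in idx[i]:
            idx[i, -1] = i
    Sp = np.add.reduce(S[idx], axis=1)
    Up = np.add.reduce(U[idx], axis=1)
    return Sp, Up


def fit_gamma(S_pooled: np.ndarray, U_pooled: np.ndarray,
              extreme_quantile: float = 0.02, min_cells: int = 10):
    """Per-gene steady-state ratio via regression through the origin.

    For each gene, cells in the bottom and top *extreme_quantile* of pooled
    spliced expression are selected and gamma = sum(u*s) / sum(s^2) over
    those cells.  Genes with fewer than *min_cells* cells carrying both
    nonzero spliced and nonzero unspliced signal are dropped; genes with no
    unspliced signal get gamma = 0 and a degenerate flag.

    Returns ``(gamma array with NaN for dropped genes, report DataFrame)``.
    """
    S, U = np.asarray(S_pooled, float), np.asarray(U_pooled, float)
    n_cells, n_genes = S.shape
    gamma = np.full(n_genes, np.nan)
    status = np.empty(n_genes, dtype=object)
    for g in range(n_genes):
        s, u = S[:, g], U[:, g]
        if (s > 0).sum() < min_cells or (u > 0).sum() < min_cells:
            if not (u > 0).any() and (s > 0).sum() >= min_cells:
                gamma[g] = 0.0
                status[g] = "degenerate"
            else:
                status[g] = "dropped"
            continue
        lo, hi = np.quantile(s, [extreme_quantile, 1 - extreme_quantile])
        sel = (s <= lo) | (s >= hi)
        denom = (s[sel] ** 2).sum()
        if denom == 0:
            status[g] = "dropped"
            continue
        gamma[g] = (u[sel] * s[sel]).sum() / denom
        status[g] = "ok"
    report = pd.DataFrame({"gene": np.arange(n_genes), "status": status,
                           "gamma": gamma})
    return gamma, report


def compute_velocity(S_pooled: np.ndarray, U_pooled: np.ndarray,
                     gamma: np.ndarray) -> np.ndarray:
    """Residual velocity v = u_pooled - gamma * s_pooled (NaN gamma -> 0)."""
    g = np.nan_to_num(np.asarray(gamma, float), nan=0.0)
    v = np.asarray(U_pooled, float) - g[None, :] * np.asarray(S_pooled, float)
    v[:, np.isnan(np.asarray(gamma, float))] = 0.0
    return v


def project_velocity(v: np.ndarray, S_pooled: np.ndarray, emb2d: np.ndarray,
                     p: VelocityParams | None = None) -> np.ndarray:
    """Project per-cell velocity vectors into a 2D embedding.

    For each cell, the velocity vector is Pearson-correlated (over genes)
    with the expression displacement to each of its n_sight nearest embedding
    neighbors; transition weights are ``exp(corr / corr_scale)`` normalized
    over neighbors, and the arrow is the weighted mean of unit embedding
    displacements minus the uniform-weight mean.  Cells with zero velocity
    get exactly zero arrows.  Arrows depend only on displacements, so they
    are invariant to global translation of the embedding.
    """
    p = p or VelocityParams()
    emb2d = np.asarray(emb2d, float)
    v = np.asarray(v, float)
    S = np.asarray(S_pooled, float)
    n = emb2d.shape[0]
    n_sight = p.n_sight
    if n_sight >= n:
        warnings.warn(
            f"n_sight={n_sight} >= n_cells={n}; capped at {n - 1}",
            stacklevel=2,
        )
        n_sight = n - 1
    nn = NearestNeighbors(n_neighbors=n_sight + 1).fit(emb2d)
    _, idx = nn.kneighbors(emb2d)

    arrows = np.zeros((n, 2))
    for i in range(n):
        nbrs = idx[i][idx[i] != i][:n_sight]
        delta_e = emb2d[nbrs] - emb2d[i]
        norm = np.linalg.norm(delta_e, axis=1)
        norm[norm == 0] = 1.0
        unit = delta_e / norm[:, None]
        baseline = unit.mean(axis=0)

        vi = v[i]
        sd_v = vi.std()
        if sd_v == 0:
            continue  # weights would be uniform; arrow = baseline - baseline
        dX = S[nbrs] - S[i]
        dXc = dX - dX.mean(axis=1, keepdims=True)
        vic = vi - vi.mean()
        num = dXc @ vic
        den = np.sqrt((dXc**2).sum(axis=1)) * np.sqrt((vic**2).sum())
        corr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        w = np.exp((corr - corr.max()) / p.corr_scale)
        w /= w.sum()
        arrows[i] = w @ unit - baseline
    return arrows


def grid_field(emb2d: np.ndarray, arrows: np.ndarray,
               grid_n: int = 30, bandwidth: float | None = None) -> GridField:
    """Kernel-average cell arrows on a grid_n x grid_n lattice.

    Gaussian distance kernel; bandwidth defaults to 1.5 grid spacings.
    ``mass`` reports the total kernel weight at each grid point so sparse
    regions can be masked.
    """
    emb2d = np.asarray(emb2d, float)
    lo, hi = emb2d.min(axis=0), emb2d.max(axis=0)
    gx = np.linspace(lo[0], hi[0], grid_n)
    gy = np.linspace(lo[1], hi[1], grid_n)
    pts = np.array([(x, y) for y in gy for x in gx])
    spacing = max((hi - lo).max() / (grid_n - 1), 1e-12)
    bw = bandwidth if bandwidth is not None else 1.5 * spacing
    d2 = ((pts[:, None, :] - emb2d[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / bw**2)
    mass = K.sum(axis=1)
    weights = K / np.maximum(mass, 1e-300)[:, None]
    return GridField(points=pts, arrows=weights @ arrows, mass=mass)


def direction_of_progression(emb2d: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit vector of increasing *t* in the embedding (per-axis covariance)."""
    emb2d = np.asarray(emb2d, float)
    t = np.asarray(t, float)
    tc = t - t.mean()
    d = np.array([np.dot(emb2d[:, 0] - emb2d[:, 0].mean(), tc),
                  np.dot(emb2d[:, 1] - emb2d[:, 1].mean(), tc)])
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("embedding carries no information about t")
    return d / norm
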
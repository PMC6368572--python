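"""Seeded synthetic single-cell datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be tested by parameter recovery without any
external data:

* negative-binomial UMI counts (gamma-Poisson, Var = mu + mu^2 * disp) over
  distinct cell populations, each with its own marker program;
* a latent pseudotime in [0, 1] with planted pseudotime-dependent genes of
  logistic / bump / linear shape and a stated log-scale amplitude;
* a planted fraction of hybrid cells whose mean program is a convex mix of
  two lineage programs (transcriptional intermediates, not doublets);
* mitochondrial-flagged genes contributing a configurable share of each
  cell's counts;
* paired spliced/unspliced matrices following two-stage transcription
  kinetics (du/dt = alpha(t) - beta*u, ds/dt = beta*u - gamma*s) with step
  alpha, sampled as Poisson counts.

Identical configuration (including seed) yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import UmiMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_spliced_unspliced",
    "draw_kinetics",
    "kinetic_moments",
    "simulate_conversion",
    "simulate_cycle_population",
    "make_qc_fixture",
    "sample_nb",
]

_DEP_SHAPES = ("logistic", "bump", "linear")


@dataclasses.dataclass
class SimConfig:
    """Parameters of a synthetic UMI dataset.

    Defaults describe a desk-scale droplet experiment: a few thousand cells at
    ~5000 UMI/cell with moderately overdispersed counts, strong lineage
    markers (tens of UMI in the expressing population, near-silent elsewhere,
    as for collagen or lysozyme genes), and mitochondrial genes carrying ~5%
    of each cell's counts, comfortably below the 8% QC ceiling.
    """

    n_cells: int = 2000
    n_genes: int = 400
    n_types: int = 1
    markers_per_type: int = 10
    lib_size_mean: float = 5000.0
    lib_size_shape: float = 20.0
    nb_dispersion: float = 0.1
    frac_dep_genes: float = 0.0
    dep_amplitude: float = 2.0
    dep_shape: str = "logistic"
    frac_hybrid: float = 0.0
    hybrid_mix_alpha: float = 2.0
    frac_mito_genes: float = 0.05
    mito_frac_counts: float = 0.05
    marker_mean: float = 10.0
    marker_off_mean: float = 0.002
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_dep_genes", "frac_hybrid", "frac_mito_genes",
                     "mito_frac_counts"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.dep_shape not in _DEP_SHAPES:
            raise ValueError(f"dep_shape must be one of {_DEP_SHAPES}")
        if self.frac_dep_genes > 0 and self.frac_dep_genes * self.n_genes < 1:
            raise ValueError(
                "frac_dep_genes * n_genes < 1: no whole gene to plant"
            )
        n_marker = self.n_types * self.markers_per_type
        if n_marker >= self.n_genes:
            raise ValueError("marker genes exhaust the gene panel")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    dep_gene_ids: list
    dep_params: pd.DataFrame  # gene, shape, amplitude, t0, width
    hybrid_cell_ids: list
    lineage: np.ndarray  # one lineage tag per cell
    pseudotime: np.ndarray  # true pseudotime in [0, 1]
    kinetics: pd.DataFrame | None = None  # gene, mode, alpha_on, beta, gamma, t_switch
    qc_fail: dict | None = None  # dialect -> {cell_id: reason}
    extras: dict = dataclasses.field(default_factory=dict)


def sample_nb(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Gamma-Poisson (negative binomial) counts with Var = mu + mu^2 * disp."""
    mean = np.asarray(mean, dtype=float)
    if size is None:
        size = mean.shape
    if dispersion == 0:
        return rng.poisson(np.broadcast_to(mean, size))
    lam = rng.gamma(shape=1.0 / dispersion,
                    scale=np.broadcast_to(mean, size) * dispersion)
    return rng.poisson(lam)


def _dep_curve(shape: str, t, t0, width):
    t = np.asarray(t, dtype=float)
    if shape == "logistic":
        return 1.0 / (1.0 + np.exp(-(t - t0) / width))
    if shape == "bump":
        return np.exp(-0.5 * ((t - t0) / width) ** 2)
    if shape == "linear":
        return t
    raise ValueError(f"unknown dep_shape {shape!r}")


def simulate_counts(config: SimConfig):
    """Simulate a UMI count matrix with planted structure.

    Returns ``(UmiMatrix, cell_meta, SimTruth)`` where ``cell_meta`` is a
    DataFrame with columns cell, cell_type, lineage, pseudotime, is_hybrid.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_cells, n_genes = cfg.n_cells, cfg.n_genes

    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)

    # --- gene panel layout: markers first, then mito, then background
    n_marker = cfg.n_types * cfg.markers_per_type
    n_mito = int(round(cfg.frac_mito_genes * n_genes))
    n_mito = min(n_mito, n_genes - n_marker - 1)
    gene_ids = np.empty(n_genes, dtype=object)
    gene_symbols = np.empty(n_genes, dtype=object)
    marker_of_type = {}
    g = 0
    for ty in range(cfg.n_types):
        idx = []
        for k in range(cfg.markers_per_type):
            gene_ids[g] = f"gene{g:05d}"
            gene_symbols[g] = f"Mk{ty}_{k}"
            idx.append(g)
            g += 1
        marker_of_type[ty] = np.array(idx)
    mito_idx = np.arange(g, g + n_mito)
    for j, gi in enumerate(mito_idx):
        gene_ids[gi] = f"gene{gi:05d}"
        gene_symbols[gi] = f"mt-Gene{j}"
    g += n_mito
    bg_idx = np.arange(g, n_genes)
    for gi in bg_idx:
        gene_ids[gi] = f"gene{gi:05d}"
        gene_symbols[gi] = f"Bg{gi}"

    # --- baseline relative expression per gene
    base = np.empty(n_genes)
    base[bg_idx] = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                     size=len(bg_idx)))
    base[mito_idx] = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                       size=len(mito_idx)))
    base[:n_marker] = cfg.marker_off_mean

    # --- planted pseudotime-dependent genes (background genes only)
    n_dep = int(round(cfg.frac_dep_genes * n_genes))
    n_dep = min(n_dep, len(bg_idx))
    dep_idx = rng.choice(bg_idx, size=n_dep, replace=False) if n_dep else \
        np.array([], dtype=int)
    dep_idx.sort()
    base[dep_idx] = 0.5  # moderately expressed baseline for planted genes
    t0s = rng.uniform(0.2, 0.8, size=n_dep)
    widths = rng.uniform(0.05, 0.1, size=n_dep)
    dep_params = pd.DataFrame(
        {
            "gene": gene_ids[dep_idx],
            "shape": cfg.dep_shape,
            "amplitude": cfg.dep_amplitude,
            "t0": t0s,
            "width": widths,
        }
    )

    # --- cells: type, hybrid status, pseudotime
    cell_type = rng.integers(0, cfg.n_types, size=n_cells)
    pseudotime = rng.uniform(0.0, 1.0, size=n_cells)
    n_hybrid = int(round(cfg.frac_hybrid * n_cells))
    hybrid_cells = rng.choice(n_cells, size=n_hybrid, replace=False) if n_hybrid \
        else np.array([], dtype=int)
    hybrid_cells.sort()
    is_hybrid = np.zeros(n_cells, dtype=bool)
    is_hybrid[hybrid_cells] = True
    if cfg.n_types > 1:
        other_type = (cell_type + rng.integers(1, cfg.n_types, size=n_cells)) \
            % cfg.n_types
    else:
        other_type = cell_type.copy()
    mix_w = rng.beta(cfg.hybrid_mix_alpha, cfg.hybrid_mix_alpha, size=n_cells)

    # --- per-cell mean program
    mean_rel = np.tile(base, (n_cells, 1))
    for ty in range(cfg.n_types):
        own = cell_type == ty
        mean_rel[np.ix_(own, marker_of_type[ty])] = cfg.marker_mean
    # hybrids: convex mix of own and partner marker programs
    for ci in hybrid_cells:
        w = mix_w[ci]
        ty, oty = cell_type[ci], other_type[ci]
        mean_rel[ci, marker_of_type[ty]] = (
            w * cfg.marker_mean + (1 - w) * cfg.marker_off_mean
        )
        if oty != ty:
            mean_rel[ci, marker_of_type[oty]] = (
                (1 - w) * cfg.marker_mean + w * cfg.marker_off_mean
            )
    # pseudotime-dependent genes: log-mean follows the planted curve with the
    # stated amplitude.  The curve is centered by its time-average so the
    # gene's overall level — and hence the library composition — stays flat
    # along pseudotime; otherwise per-cell renormalization would divide part
    # of the planted amplitude back out of every gene.
    if n_dep:
        curves = np.stack(
            [_dep_curve(cfg.dep_shape, pseudotime, t0s[j], widths[j])
             for j in range(n_dep)],
            axis=1,
        )  # cells x dep genes
        curves = curves - curves.mean(axis=0, keepdims=True)
        mean_rel[:, dep_idx] = mean_rel[:, dep_idx] * np.exp(
            cfg.dep_amplitude * curves
        )

    # mito genes carry a fixed expected share of each cell's counts
    if n_mito and cfg.mito_frac_counts > 0:
        non_mito = np.ones(n_genes, dtype=bool)
        non_mito[mito_idx] = False
        s_other = mean_rel[:, non_mito].sum(axis=1)
        s_mito = mean_rel[:, mito_idx].sum(axis=1)
        target = cfg.mito_frac_counts / (1.0 - cfg.mito_frac_counts)
        mean_rel[:, mito_idx] *= (target * s_other / s_mito)[:, None]

    # --- library sizes and renormalization, then gamma-Poisson sampling
    lib = rng.gamma(cfg.lib_size_shape,
                    cfg.lib_size_mean / cfg.lib_size_shape, size=n_cells)
    mu = mean_rel * (lib / mean_rel.sum(axis=1))[:, None]
    counts = sample_nb(rng, mu, cfg.nb_dispersion)

    m = UmiMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
                  gene_symbols=gene_symbols)
    lineage = np.array([f"type{t}" for t in cell_type], dtype=object)
    meta = pd.DataFrame(
        {
            "cell": cell_ids,
            "cell_type": lineage,
            "lineage": lineage,
            "pseudotime": pseudotime,
            "is_hybrid": is_hybrid,
        }
    )
    truth = SimTruth(
        dep_gene_ids=list(gene_ids[dep_idx]),
        dep_params=dep_params,
        hybrid_cell_ids=list(cell_ids[hybrid_cells]),
        lineage=lineage,
        pseudotime=pseudotime,
        extras={
            "marker_symbols_by_type": {
                f"type{ty}": list(gene_symbols[marker_of_type[ty]])
                for ty in range(cfg.n_types)
            },
            "mix_weight": mix_w,
        },
    )
    return m, meta, truth


# ---------------------------------------------------------------------------
# spliced / unspliced kinetics
# ---------------------------------------------------------------------------

def kinetic_moments(t, mode: str, alpha_on: float, beta: float, gamma: float,
                    t_switch: float):
    """Exact u(t), s(t) of the two-stage model with a step transcription rate.

    induced:   alpha = 0 before t_switch, alpha_on after; u = s = 0 at switch.
    repressed: alpha = alpha_on before t_switch (system at steady state),
               0 after.
    steady:    alpha = alpha_on for all t.
    """
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be > 0")
    t = np.asarray(t, dtype=float)
    a, b, g = alpha_on, beta, gamma
    u_ss, s_ss = a / b, a / g
    d = t - t_switch

    def _mix_term(dd):
        # a * (e^{-b dd} - e^{-g dd}) / (g - b), with the b -> g limit
        if abs(b - g) < 1e-8:
            return a * dd * np.exp(-g * dd)
        return a * (np.exp(-b * dd) - np.exp(-g * dd)) / (g - b)

    if mode == "steady":
        return np.full_like(t, u_ss), np.full_like(t, s_ss)
    if mode == "induced":
        dd = np.maximum(d, 0.0)
        u = u_ss * (1.0 - np.exp(-b * dd))
        s = s_ss * (1.0 - np.exp(-g * dd)) - _mix_term(dd)
        u = np.where(d < 0, 0.0, u)
        s = np.where(d < 0, 0.0, np.maximum(s, 0.0))
        return u, s
    if mode == "repressed":
        dd = np.maximum(d, 0.0)
        u = u_ss * np.exp(-b * dd)
        s = s_ss * np.exp(-g * dd) + _mix_term(dd)
        u = np.where(d < 0, u_ss, u)
        s = np.where(d < 0, s_ss, s)
        return u, s
    raise ValueError(f"unknown kinetic mode {mode!r}")


def draw_kinetics(n_genes: int, seed: int, modes: Sequence[str] = ("induced",
                  "repressed"), alpha_range=(20.0, 60.0),
                  beta_range=(6.0, 12.0), gamma_range=(2.0, 6.0),
                  switch_range=(0.0, 0.9)) -> pd.DataFrame:
    """Draw a per-gene kinetics table with staggered switch times."""
    rng = np.random.default_rng(seed)
    mode = np.array([modes[i % len(modes)] for i in range(n_genes)],
                    dtype=object)
    return pd.DataFrame(
        {
            "gene": [f"gene{i:05d}" for i in range(n_genes)],
            "mode": mode,
            "alpha_on": rng.uniform(*alpha_range, size=n_genes),
            "beta": rng.uniform(*beta_range, size=n_genes),
            "gamma": rng.uniform(*gamma_range, size=n_genes),
            "t_switch": rng.uniform(*switch_range, size=n_genes),
        }
    )


def simulate_spliced_unspliced(config: SimConfig, kinetics: pd.DataFrame,
                               count_scale: float = 1.0):
    """Sample paired spliced/unspliced Poisson counts from step kinetics.

    Each cell sits at its true pseudotime; per gene, u(t) and s(t) are the
    exact solutions of the two-stage model and counts are
    Poisson(count_scale * u) and Poisson(count_scale * s).

    Returns ``(spliced UmiMatrix, unspliced UmiMatrix, SimTruth)``.
    """
    cfg = config
    required = {"gene", "mode", "alpha_on", "beta", "gamma", "t_switch"}
    if not required.issubset(kinetics.columns):
        raise ValueError(f"kinetics table needs columns {sorted(required)}")
    if (kinetics["beta"] <= 0).any() or (kinetics["gamma"] <= 0).any():
        raise ValueError("beta and gamma must be > 0 for every gene")
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.n_cells
    n_genes = len(kinetics)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    gene_ids = kinetics["gene"].to_numpy(dtype=object)
    t = rng.uniform(0.0, 1.0, size=n_cells)

    U = np.empty((n_cells, n_genes))
    S = np.empty((n_cells, n_genes))
    for j, row in enumerate(kinetics.itertuples(index=False)):
        U[:, j], S[:, j] = kinetic_moments(
            t, row.mode, row.alpha_on, row.beta, row.gamma, row.t_switch
        )
    spliced = rng.poisson(count_scale * S)
    unspliced = rng.poisson(count_scale * U)

    kw = dict(cell_ids=cell_ids, gene_ids=gene_ids)
    sm = UmiMatrix(counts=spliced, **kw)
    um = UmiMatrix(counts=unspliced, **kw)
    truth = SimTruth(
        dep_gene_ids=[],
        dep_params=pd.DataFrame(),
        hybrid_cell_ids=[],
        lineage=np.array(["lin"] * n_cells, dtype=object),
        pseudotime=t,
        kinetics=kinetics.copy(),
        extras={"count_scale": count_scale, "U": U, "S": S},
    )
    return sm, um, truth


def simulate_conversion(n_cells: int = 1500, n_genes: int = 120,
                        seed: int = 0, count_scale: float = 1.0,
                        mix_width: float = 0.02, steady_state: bool = False):
    """Two-lineage conversion dataset for velocity testing.

    Cells sit on a single latent progression t in [0, 1]; lineage A (the
    starting identity) dominates early t and lineage B late t.  Across the
    planted overlap window t in [0.4, 0.6] — the middle two of ten equal
    pseudotime bins — the two lineages mix 50/50, with ramps of width
    *mix_width* on either side.  Kinetic genes have staggered switch times, so at
    every t some genes are actively inducing or shutting down and the velocity
    field points toward increasing t.  With ``steady_state=True`` all switches
    are moved far into the past: expression still varies across genes but no
    gene is out of equilibrium, giving a directionless null field.

    Returns ``(spliced, unspliced, meta, truth)``.
    """
    kin = draw_kinetics(n_genes, seed=seed + 1)
    if steady_state:
        kin = kin.assign(mode="steady")
    cfg = SimConfig(n_cells=n_cells, n_genes=n_genes, seed=seed)
    sm, um, truth = simulate_spliced_unspliced(cfg, kin,
                                               count_scale=count_scale)
    rng = np.random.default_rng(seed + 2)
    t = truth.pseudotime
    w = mix_width
    p_b = np.interp(t, [0.0, 0.4 - w, 0.4, 0.6, 0.6 + w, 1.0],
                    [0.02, 0.02, 0.5, 0.5, 0.98, 0.98])
    lineage = np.where(rng.uniform(size=n_cells) < p_b, "fibroblast",
                       "myeloid").astype(object)
    truth.extras["overlap_window"] = (0.4, 0.6)
    truth.lineage = lineage
    meta = pd.DataFrame(
        {
            "cell": sm.cell_ids,
            "lineage": lineage,
            "pseudotime": t,
        }
    )
    return sm, um, meta, truth


# ---------------------------------------------------------------------------
# focused fixtures
# ---------------------------------------------------------------------------

def simulate_two_waves(n_cells: int = 2000, n_genes: int = 300,
                       n_per_wave: int = 40, t0_early: float = 0.3,
                       t0_late: float = 0.7, width: float = 0.15,
                       amplitude: float = 2.5, lib_size_mean: float = 5000.0,
                       nb_dispersion: float = 0.1, seed: int = 0):
    """Counts with two planted temporal waves of pseudotime-dependent genes.

    Each wave is a group of genes whose log-mean follows a Gaussian bump
    centered near *t0_early* or *t0_late* (small per-gene jitter), centered
    by its time-average so the library composition stays flat.  The
    remaining genes are static lognormal background.

    Returns ``(UmiMatrix, meta, SimTruth)``; ``truth.extras["wave"]`` maps
    each planted gene id to "early" or "late".
    """
    rng = np.random.default_rng(seed)
    n_dep = 2 * n_per_wave
    if n_dep >= n_genes:
        raise ValueError("wave genes exhaust the gene panel")
    t = rng.uniform(0.0, 1.0, size=n_cells)
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)], dtype=object)
    base = np.exp(rng.normal(-0.7, 1.0, size=n_genes))
    dep_idx = np.arange(n_dep)
    base[dep_idx] = 0.5
    t0s = np.concatenate([
        t0_early + rng.uniform(-0.03, 0.03, n_per_wave),
        t0_late + rng.uniform(-0.03, 0.03, n_per_wave),
    ])
    wave = np.array(["early"] * n_per_wave + ["late"] * n_per_wave,
                    dtype=object)
    mean_rel = np.tile(base, (n_cells, 1))
    curves = np.exp(-0.5 * ((t[:, None] - t0s[None, :]) / width) ** 2)
    curves -= curves.mean(axis=0, keepdims=True)
    mean_rel[:, dep_idx] *= np.exp(amplitude * curves)
    lib = rng.gamma(20.0, lib_size_mean / 20.0, size=n_cells)
    mu = mean_rel * (lib / mean_rel.sum(axis=1))[:, None]
    counts = sample_nb(rng, mu, nb_dispersion)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    m = UmiMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids)
    meta = pd.DataFrame({"cell": cell_ids, "pseudotime": t})
    truth = SimTruth(
        dep_gene_ids=list(gene_ids[dep_idx]),
        dep_params=pd.DataFrame(
            {"gene": gene_ids[dep_idx], "shape": "bump",
             "amplitude": amplitude, "t0": t0s, "width": width}
        ),
        hybrid_cell_ids=[],
        lineage=np.array(["lin"] * n_cells, dtype=object),
        pseudotime=t,
        extras={"wave": dict(zip(gene_ids[dep_idx], wave))},
    )
    return m, meta, truth


def simulate_cycle_population(g1s_genes: Sequence[str],
                              g2m_genes: Sequence[str],
                              phase_fracs=(0.6, 0.2, 0.2),
                              n_cells: int = 600, n_background: int = 300,
                              boost: float = 6.0, seed: int = 0):
    """Cells with planted cycle phases over real phase gene symbols.

    Phase fractions are (G1, S, G2/M).  S cells have the G1/S set boosted
    *boost*-fold, G2/M cells the G2/M set; G1 cells express both sets at
    baseline.  Returns ``(UmiMatrix, planted phase array)``.
    """
    rng = np.random.default_rng(seed)
    fr = np.asarray(phase_fracs, dtype=float)
    if fr.shape != (3,) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("phase_fracs must be 3 fractions summing to 1")
    phases = rng.choice(np.array(["G1", "S", "G2M"], dtype=object),
                        size=n_cells, p=fr)
    symbols = (list(g1s_genes) + list(g2m_genes)
               + [f"Bg{i}" for i in range(n_background)])
    n_genes = len(symbols)
    base = np.exp(rng.normal(-0.2, 0.6, size=n_genes))
    mean = np.tile(base, (n_cells, 1))
    g1s_cols = np.arange(len(g1s_genes))
    g2m_cols = np.arange(len(g1s_genes), len(g1s_genes) + len(g2m_genes))
    mean[np.ix_(phases == "S", g1s_cols)] *= boost
    mean[np.ix_(phases == "G2M", g2m_cols)] *= boost
    lib = 4000.0
    mu = mean * (lib / mean.sum(axis=1))[:, None]
    counts = sample_nb(rng, mu, 0.1)
    m = UmiMatrix(
        counts=counts,
        cell_ids=np.array([f"cell{i:04d}" for i in range(n_cells)],
                          dtype=object),
        gene_ids=np.array([f"gene{i:04d}" for i in range(n_genes)],
                          dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
    )
    return m, phases


def _fill_cell(rng, n_genes, mito_cols, reserved_cols, total, n_detect,
               mito_frac):
    """One cell's counts with exact total, detected-gene count and mito share.

    ``reserved_cols`` are never touched (sentinel genes placed separately).
    """
    counts = np.zeros(n_genes, dtype=np.int64)
    mito_total = int(round(total * mito_frac))
    other_total = total - mito_total
    n_mito_detect = 1 if mito_total else 0
    usable = np.setdiff1d(np.arange(n_genes),
                          np.concatenate([mito_cols, reserved_cols]))
    n_other_detect = n_detect - n_mito_detect
    cols = rng.choice(usable, size=n_other_detect, replace=False)
    counts[cols] = 1
    remaining = other_total - n_other_detect
    if remaining > 0:
        extra = rng.choice(cols, size=remaining, replace=True)
        np.add.at(counts, extra, 1)
    if mito_total:
        mcol = rng.choice(mito_cols)
        counts[mcol] = mito_total
    assert counts.sum() == total and (counts > 0).sum() == n_detect
    return counts


def make_qc_fixture(seed: int = 0):
    """Small matrix with deliberate violations of every QC rule.

    The fixture (~40 cells, enough genes to trip the full-length gene-count
    rule) contains, for both QC dialects, one cell per failure reason plus
    boundary cells sitting exactly on each threshold, and sentinel genes
    exercising the genes-in-<3-cells rule, including one whose third
    supporting cell itself fails cell QC.  Expected labels are recorded in
    ``SimTruth.qc_fail`` as ``{"droplet": {...}, "fulllength": {...}}`` and
    the expected full-length gene removals in
    ``truth.extras["fulllength_removed_genes"]``.
    """
    rng = np.random.default_rng(seed)
    n_genes = 11050
    mito_cols = np.arange(n_genes - 20, n_genes)  # symbols mt-*
    plans = []  # (name, total, n_detect, mito_frac, droplet_reason, fl_reason)

    for i in range(24):
        plans.append((f"ok{i:02d}", 3000 + 50 * i, 300 + 10 * i, 0.04, "", ""))
    # droplet rule violations and boundaries
    plans.append(("umi_hi", 9000, 400, 0.04, "umi", ""))
    plans.append(("umi_edge", 8000, 400, 0.04, "umi", ""))  # == 8000: removed
    plans.append(("umi_below", 7999, 400, 0.04, "", ""))
    plans.append(("genes_hi", 4000, 2600, 0.04, "genes", ""))
    plans.append(("genes_edge", 4000, 2500, 0.04, "genes", ""))  # == 2500: removed
    plans.append(("genes_below", 4000, 2499, 0.04, "", ""))
    plans.append(("mito_hi", 3000, 300, 0.10, "mito", ""))
    plans.append(("mito_edge", 3000, 300, 0.08, "", ""))  # == 8%: kept
    # full-length rule violations and boundaries
    plans.append(("fl_genes_hi", 25000, 11001, 0.04, "umi+genes", "genes"))
    plans.append(("fl_genes_edge", 25000, 11000, 0.04, "umi+genes", ""))
    plans.append(("fl_mito_hi", 3000, 300, 0.16, "mito", "mito"))
    plans.append(("fl_mito_edge", 3000, 300, 0.15, "mito", ""))  # == 15%: kept

    reserved_cols = np.arange(3)  # sentinel genes for the <3-cells rule
    counts = np.zeros((len(plans), n_genes), dtype=np.int64)
    for i, (_, total, ndet, mfrac, _, _) in enumerate(plans):
        counts[i] = _fill_cell(rng, n_genes, mito_cols, reserved_cols,
                               total, ndet, mfrac)

    cell_ids = np.array([p[0] for p in plans], dtype=object)
    fl_pass = np.array([p[5] == "" for p in plans])

    # sentinel genes exercising the genes-in-<3-cells rule; adding one count
    # to a cell shifts its total by <= 1, far from every planned boundary
    # except the exact-threshold cells, which are therefore never supports
    sentinels = {
        "sent_keep3": 3,   # expressed in 3 surviving cells -> kept
        "sent_drop2": 2,   # expressed in 2 surviving cells -> removed
        "sent_lostcell": 3,  # 3 cells, one of which fails cell QC -> removed
    }
    sent_cols = {}
    surviving = np.where(fl_pass)[0]
    failing = np.where(~fl_pass)[0]
    for col, (name, n_support) in enumerate(sentinels.items()):
        sent_cols[name] = col
        if name == "sent_lostcell":
            support = list(surviving[6:8]) + [failing[0]]
        else:
            support = list(surviving[:n_support])
        for ci in support:
            counts[ci, col] = 1

    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)], dtype=object)
    gene_symbols = gene_ids.copy()
    for name, c in sent_cols.items():
        gene_symbols[c] = name
    for j, c in enumerate(mito_cols):
        gene_symbols[c] = f"mt-Gene{j}"

    m = UmiMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids,
                  gene_symbols=gene_symbols)

    # independent label arithmetic (plain sums, not the qc module)
    totals = counts.sum(axis=1)
    ndet = (counts > 0).sum(axis=1)
    mfrac = counts[:, mito_cols].sum(axis=1) / totals
    droplet, fulllength = {}, {}
    for i, cid in enumerate(cell_ids):
        reasons = []
        if totals[i] >= 8000:
            reasons.append("umi")
        if ndet[i] >= 2500:
            reasons.append("genes")
        if mfrac[i] > 0.08:
            reasons.append("mito")
        if reasons:
            droplet[cid] = "+".join(reasons)
        reasons = []
        if ndet[i] > 11000:
            reasons.append("genes")
        if mfrac[i] > 0.15:
            reasons.append("mito")
        if reasons:
            fulllength[cid] = "+".join(reasons)

    keep = np.array([c not in fulllength for c in cell_ids])
    support = (counts[keep] > 0).sum(axis=0)
    fl_removed = list(gene_ids[support < 3])

    truth = SimTruth(
        dep_gene_ids=[],
        dep_params=pd.DataFrame(),
        hybrid_cell_ids=[],
        lineage=np.array(["na"] * len(cell_ids), dtype=object),
        pseudotime=np.zeros(len(cell_ids)),
        qc_fail={"droplet": droplet, "fulllength": fulllength},
        extras={
            "fulllength_removed_genes": fl_removed,
            "sentinel_genes": {k: gene_ids[v] for k, v in sent_cols.items()},
        },
    )
    return m, truth
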
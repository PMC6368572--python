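import numpy as np
import pytest
from scipy.interpolate import CubicSpline
from scipy.stats import spearmanr

from scwound.cluster import run_pca
from scwound.qc import ExprMatrix, normalize_log, select_hvg
from scwound.pseudotime import (GeneTestResults, PseudotimeAssignment,
                                PtDepParams, bin_composition, bin_pseudotime,
                                cluster_dep_genes,
                                estimate_pseudotime_fallback,
                                natural_spline_basis, smooth_profile,
                                spline_hat_matrix, trimean, trimean_profile)
from scwound.pseudotime import test_pseudotime_dependence as ptdep
from scwound.simulate import SimConfig, simulate_counts


def _expr_from_values(values):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExprMatrix(
        values=values,
        norm_counts=np.expm1(values),
        scale_factor=1e4,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        gene_symbols=np.array([f"g{j}" for j in range(g)], dtype=object),
    )


class TestBinPseudotime:
    def test_boundaries(self):
        t = np.array([0.0, 0.05, 0.95, 1.0])
        bins = bin_pseudotime(t, 10)
        assert bins[0] == 1 and bins[-1] == 10

    def test_uniform_occupancy(self, rng):
        t = rng.uniform(size=10_000)
        bins = bin_pseudotime(t, 10)
        counts = np.bincount(bins)[1:]
        # binomial error around 1000 per bin
        assert np.all(np.abs(counts - 1000) < 4 * np.sqrt(1000 * 0.9))

    def test_edges_match_linspace(self, rng):
        t = rng.uniform(2.0, 5.0, size=500)
        bins = bin_pseudotime(t, 7)
        edges = np.linspace(t.min(), t.max(), 8)
        expect = np.minimum(np.searchsorted(edges, t, side="right"), 7)
        # searchsorted treats t == edge differently at interior edges only
        # when a value sits exactly on one; none do for continuous draws
        np.testing.assert_array_equal(bins, expect)

    def test_constant_t_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            bin_pseudotime(np.full(5, 0.3), 10)


class TestTrimean:
    def test_constant_values(self):
        assert trimean(np.full(7, 4.2)) == pytest.approx(4.2)

    def test_symmetric_values(self):
        assert trimean(np.array([1, 2, 3, 4, 5])) == pytest.approx(3.0)

    def test_skewed_values_match_hand_quartiles(self):
        # {0,0,0,10}: Q1 = 0, Q2 = 0, Q3 = 2.5 by linear interpolation
        x = np.array([0.0, 0, 0, 10])
        assert trimean(x) == pytest.approx((0 + 2 * 0 + 2.5) / 4)

    def test_empty_bin_interpolated_and_flagged(self):
        vals = np.arange(10, dtype=float).reshape(-1, 1)
        e = _expr_from_values(np.tile(vals, (1, 2)))
        bins = np.array([1, 1, 2, 2, 3, 3, 5, 5, 5, 5])  # bin 4 empty
        prof, empty = trimean_profile(e, "g0", bins, n_bins=5)
        assert empty.tolist() == [False, False, False, True, False]
        np.testing.assert_allclose(prof[3], (prof[2] + prof[4]) / 2)


class TestSmoothProfile:
    def test_reproduces_constants(self):
        np.testing.assert_allclose(smooth_profile(np.full(10, 2.5), 5), 2.5)

    def test_reproduces_linear(self):
        x = np.arange(1, 11, dtype=float)
        np.testing.assert_allclose(smooth_profile(3 * x - 1, 5), 3 * x - 1,
                                   atol=1e-10)

    def test_matches_independent_basis_regression(self, rng):
        # oracle: natural-cubic cardinal interpolants span the same space
        y = rng.normal(size=10)
        x = np.arange(1, 11, dtype=float)
        df = 5
        knots = np.quantile(x, np.linspace(0, 1, df))
        B = np.column_stack([
            CubicSpline(knots, np.eye(df)[j], bc_type="natural")(x)
            for j in range(df)
        ])
        beta = np.linalg.lstsq(B, y, rcond=None)[0]
        np.testing.assert_allclose(smooth_profile(y, df), B @ beta,
                                   atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.array([1.0, np.nan, 2, 3, 4]), 3)


class TestPermutationTest:
    @pytest.fixture(scope="class")
    def dep_results(self):
        cfg = SimConfig(n_cells=1200, n_genes=150, frac_dep_genes=0.2,
                        dep_amplitude=2.0, seed=21)
        m, _, truth = simulate_counts(cfg)
        e = normalize_log(m)
        t = PseudotimeAssignment(truth.pseudotime, source="truth")
        with pytest.warns(UserWarning, match="Bonferroni"):
            res = ptdep(
                e, t, PtDepParams(n_perms=100, seed=0)
            )
        return res, truth

    def test_constant_gene_zero_sd(self):
        vals = np.ones((200, 2))
        vals[:, 1] = np.linspace(0, 3, 200)
        e = _expr_from_values(vals)
        t = PseudotimeAssignment(np.linspace(0, 1, 200))
        res = ptdep(
            e, t, PtDepParams(n_perms=20, seed=0, min_expr_frac=0.0)
        )
        row = res.table.set_index("gene").loc["g0"]
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)
        assert not row["significant"]

    def test_observed_beats_all_perms_gives_p_zero(self):
        rng = np.random.default_rng(0)
        vals = np.column_stack([
            np.linspace(0, 5, 300) + rng.normal(0, 0.1, 300),
            rng.normal(1, 0.1, 300).clip(0),
        ])
        e = _expr_from_values(np.clip(vals, 0, None))
        t = PseudotimeAssignment(np.linspace(0, 1, 300))
        res = ptdep(
            e, t, PtDepParams(n_perms=50, seed=1, min_expr_frac=0.0)
        )
        row = res.table.set_index("gene").loc["g0"]
        assert row["pval"] == 0.0 and row["padj"] == 0.0
        assert row["significant"]

    def test_planted_genes_detected(self, dep_results):
        res, truth = dep_results
        tab = res.table.set_index("gene")
        assert tab.loc[truth.dep_gene_ids, "significant"].mean() >= 0.8

    def test_null_genes_clean(self, dep_results):
        res, truth = dep_results
        tab = res.table.set_index("gene")
        null = tab.drop(index=truth.dep_gene_ids, errors="ignore")
        assert null["significant"].sum() == 0

    def test_determinism(self, dep_results):
        res, truth = dep_results
        cfg = SimConfig(n_cells=1200, n_genes=150, frac_dep_genes=0.2,
                        dep_amplitude=2.0, seed=21)
        m, _, truth2 = simulate_counts(cfg)
        e = normalize_log(m)
        t = PseudotimeAssignment(truth2.pseudotime, source="truth")
        with pytest.warns(UserWarning):
            res2 = ptdep(
                e, t, PtDepParams(n_perms=100, seed=0)
            )
        np.testing.assert_array_equal(res.table["pval"], res2.table["pval"])
        np.testing.assert_allclose(res.smoothed_profiles,
                                   res2.smoothed_profiles)

    def test_location_scale_equivariance(self):
        rng = np.random.default_rng(3)
        base = np.clip(rng.normal(2, 0.5, size=(300, 1)), 0, None)
        t = PseudotimeAssignment(rng.uniform(size=300))
        p = PtDepParams(n_perms=10, seed=0, min_expr_frac=0.0)
        sd0 = ptdep(
            _expr_from_values(base), t, p).table["sd"][0]
        sd_shift = ptdep(
            _expr_from_values(base + 5), t, p).table["sd"][0]
        sd_scale = ptdep(
            _expr_from_values(base * 3), t, p).table["sd"][0]
        assert sd_shift == pytest.approx(sd0, rel=1e-9)
        assert sd_scale == pytest.approx(3 * sd0, rel=1e-9)

    def test_null_pvalues_super_uniform(self):
        # P(p_perm <= q) <= q + 1/n_perms under exchangeability
        rng = np.random.default_rng(5)
        vals = np.clip(rng.normal(1, 0.4, size=(400, 60)), 0, None)
        e = _expr_from_values(vals)
        t = PseudotimeAssignment(rng.uniform(size=400))
        res = ptdep(
            e, t, PtDepParams(n_perms=50, seed=2, min_expr_frac=0.0)
        )
        pv = res.table["pval"].to_numpy()
        for q in (0.05, 0.1, 0.25):
            frac = (pv <= q).mean()
            # three-sigma binomial slack on 60 genes
            slack = 3 * np.sqrt(q * (1 - q) / 60)
            assert frac <= q + 1 / 50 + slack


class TestClusterDepGenes:
    def _results_from_profiles(self, profiles, significant=None):
        profiles = np.asarray(profiles, dtype=float)
        n = len(profiles)
        import pandas as pd

        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "sd": 1.0,
                "pval": 0.0,
                "padj": 0.0,
                "significant": significant if significant is not None
                else [True] * n,
                "cluster": "",
            }
        )
        return GeneTestResults(
            table=table,
            trimean_profiles=profiles,
            smoothed_profiles=profiles,
            bin_centers=np.arange(profiles.shape[1], dtype=float),
            params=PtDepParams(),
        )

    def test_duplicated_profile_single_cluster(self, rng):
        prof = np.sin(np.linspace(0, np.pi, 10))
        profiles = np.tile(prof, (6, 1)) + rng.normal(0, 1e-6, (6, 10))
        res = self._results_from_profiles(profiles)
        labels = cluster_dep_genes(res, n_gene_clusters=1)
        assert set(labels) == {"pC1"}

    def test_two_waves_separated_and_ordered(self, rng):
        x = np.linspace(0, 1, 10)
        early = np.exp(-0.5 * ((x - 0.2) / 0.15) ** 2)
        late = np.exp(-0.5 * ((x - 0.8) / 0.15) ** 2)
        profiles = np.vstack(
            [early + rng.normal(0, 0.03, 10) for _ in range(20)]
            + [late + rng.normal(0, 0.03, 10) for _ in range(20)]
        )
        res = self._results_from_profiles(profiles)
        labels = cluster_dep_genes(res, n_gene_clusters=2)
        early_labels = labels.iloc[:20]
        late_labels = labels.iloc[20:]
        # earliest-peaking cluster must be pC1 and waves must separate
        assert (early_labels == "pC1").mean() >= 0.95
        assert (late_labels == "pC2").mean() >= 0.95

    def test_too_few_significant_genes(self):
        res = self._results_from_profiles(np.ones((3, 10)),
                                          significant=[True, False, False])
        with pytest.raises(ValueError, match="1 significant"):
            cluster_dep_genes(res, n_gene_clusters=2)


class TestBinComposition:
    def test_single_label_all_ones(self, rng):
        t = rng.uniform(size=100)
        comp = bin_composition(np.array(["x"] * 100), t, n_bins=5)
        np.testing.assert_allclose(comp["x"], 1.0)

    def test_fractions_sum_to_one(self, rng):
        t = rng.uniform(size=200)
        labels = rng.choice(["a", "b", "c"], size=200)
        comp = bin_composition(labels, t, n_bins=10)
        occupied = comp["n_cells"] > 0
        np.testing.assert_allclose(
            comp.loc[occupied, ["a", "b", "c"]].sum(axis=1), 1.0
        )

    def test_disjoint_halves(self, rng):
        t = np.concatenate([rng.uniform(0, 0.5, 300),
                            rng.uniform(0.5, 1.0, 300)])
        labels = np.array(["A"] * 300 + ["B"] * 300)
        comp = bin_composition(labels, t, n_bins=10)
        np.testing.assert_allclose(comp.loc[1:5, "A"], 1.0)
        np.testing.assert_allclose(comp.loc[6:10, "B"], 1.0)


class TestFallbackPseudotime:
    def test_cells_on_a_line(self, rng):
        pos = rng.uniform(size=50)
        coords = np.column_stack([pos * 10, np.zeros(50), np.zeros(50)])
        t = estimate_pseudotime_fallback(coords)
        assert abs(spearmanr(t.values, pos)[0]) > 0.999

    def test_reversal_flag(self, rng):
        coords = rng.normal(size=(60, 3))
        coords[:, 0] = np.linspace(0, 5, 60)
        fwd = estimate_pseudotime_fallback(coords)
        rev = estimate_pseudotime_fallback(coords, reverse=True)
        np.testing.assert_allclose(fwd.values, 1 - rev.values, atol=1e-9)

    def test_recovers_planted_ordering(self):
        cfg = SimConfig(n_cells=800, n_genes=200, frac_dep_genes=0.3,
                        dep_amplitude=2.5, seed=13)
        m, _, truth = simulate_counts(cfg)
        e = normalize_log(m)
        hvg, _ = select_hvg(e)
        emb = run_pca(e, hvg, n_pcs=10)
        t = estimate_pseudotime_fallback(emb)
        rho = spearmanr(t.values, truth.pseudotime)[0]
        assert abs(rho) >= 0.8

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="10 cells"):
            estimate_pseudotime_fallback(np.zeros((5, 3)))
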
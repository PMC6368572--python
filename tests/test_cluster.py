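import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2, norm
from sklearn.metrics import adjusted_rand_score

from scwound.cluster import (ClusterParams, CycleGeneSets, cluster_graph,
                             cluster_relatedness, cluster_signatures,
                             cross_correlate_signatures, linkage_to_newick,
                             load_mouse_cycle_genes, rank_markers_lrt,
                             run_pca, score_cell_cycle)
from scwound.io import UmiMatrix
from scwound.qc import ExprMatrix, normalize_log, select_hvg
from scwound.simulate import simulate_cycle_population


def _expr(values, gene_ids=None, symbols=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    return ExprMatrix(
        values=values,
        norm_counts=np.expm1(values),
        scale_factor=1e4,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
        gene_symbols=np.array(symbols or gene_ids, dtype=object),
    )


class TestRunPca:
    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=6)
        e = _expr(np.outer(u, v) + 5)
        emb = run_pca(e, list(e.gene_ids), n_pcs=2)
        assert emb.explained_variance_ratio[0] > 0.999

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 8))
        e = _expr(X)
        emb = run_pca(e, list(e.gene_ids), n_pcs=3)
        perm = rng.permutation(30)
        e2 = _expr(X[perm])
        emb2 = run_pca(e2, list(e2.gene_ids), n_pcs=3)
        np.testing.assert_allclose(emb2.coords, emb.coords[perm], atol=1e-8)

    def test_variances_match_eigendecomposition(self, rng):
        # oracle: direct eigensolve of the scaled covariance matrix
        X = rng.normal(size=(20, 10))
        e = _expr(X)
        emb = run_pca(e, list(e.gene_ids), n_pcs=5)
        Xs = (X - X.mean(0)) / X.std(0)
        evals = np.sort(np.linalg.eigvalsh(Xs.T @ Xs))[::-1]
        np.testing.assert_allclose(
            emb.explained_variance_ratio, (evals / evals.sum())[:5], atol=1e-10
        )

    def test_constant_gene_dropped_with_warning(self, rng):
        X = rng.normal(size=(15, 5))
        X[:, 2] = 1.0
        e = _expr(X)
        with pytest.warns(UserWarning, match="constant"):
            emb = run_pca(e, list(e.gene_ids), n_pcs=2)
        assert "g2" not in emb.gene_ids


class TestClusterGraph:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(size=(60, 5))
        b = rng.normal(size=(60, 5)) + 10  # 10 SD separation
        coords = np.vstack([a, b])
        from scwound.cluster import Embedding

        emb = Embedding(coords=coords, explained_variance_ratio=np.ones(5),
                        loadings=np.zeros((1, 5)),
                        gene_ids=np.array(["g"], dtype=object),
                        cell_ids=np.array([f"c{i}" for i in range(120)],
                                          dtype=object))
        labels = cluster_graph(emb, ClusterParams(n_pcs=5, knn_k=15,
                                                  resolution=0.5, seed=0))
        assert len(set(labels)) == 2
        truth = np.array([0] * 60 + [1] * 60)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_low_resolution(self, rng):
        from scwound.cluster import Embedding

        coords = rng.normal(size=(100, 4))
        emb = Embedding(coords=coords, explained_variance_ratio=np.ones(4),
                        loadings=np.zeros((1, 4)),
                        gene_ids=np.array(["g"], dtype=object),
                        cell_ids=np.array([f"c{i}" for i in range(100)],
                                          dtype=object))
        labels = cluster_graph(emb, ClusterParams(n_pcs=4, knn_k=20,
                                                  resolution=0.05, seed=0))
        assert len(set(labels)) == 1

    def test_four_type_recovery_and_determinism(self, four_type_sim):
        m, meta, truth = four_type_sim
        e = normalize_log(m)
        hvg, _ = select_hvg(e)
        emb = run_pca(e, hvg, n_pcs=15)
        p = ClusterParams(n_pcs=15, knn_k=20, resolution=0.45, seed=1)
        labels = cluster_graph(emb, p)
        assert adjusted_rand_score(truth.lineage, labels) >= 0.9
        np.testing.assert_array_equal(labels, cluster_graph(emb, p))


class TestRankMarkersLrt:
    def test_planted_marker_reported(self, four_type_sim):
        m, meta, truth = four_type_sim
        e = normalize_log(m)
        labels = meta["cell_type"].to_numpy()
        table = rank_markers_lrt(e, labels)
        mk0 = truth.extras["marker_symbols_by_type"]["type0"][0]
        gid = m.gene_ids[list(m.gene_symbols).index(mk0)]
        row = table[(table["gene"] == gid) & (table["cluster"] == "type0")]
        assert row["is_marker"].all()
        assert (row["log_fc"] > 0.25).all() and (row["p_value"] < 1e-10).all()

    def test_identical_distributions_not_reported(self, rng):
        x = np.abs(rng.normal(1, 0.3, size=(200, 3)))
        e = _expr(x)
        labels = np.array(["a"] * 100 + ["b"] * 100)
        table = rank_markers_lrt(e, labels)
        assert not table["is_marker"].any()

    def test_statistic_matches_numeric_mle(self, rng):
        # oracle: direct numeric maximization of the stated likelihood
        x_in = np.concatenate([np.zeros(12), rng.normal(2.0, 0.5, 28)])
        x_out = np.concatenate([np.zeros(30), rng.normal(1.0, 0.7, 10)])

        def negll(params, x):
            pi, mu, log_sd = params
            sd = np.exp(log_sd)
            n1 = (x > 0).sum()
            n0 = len(x) - n1
            ll = n0 * np.log(1 - pi) + n1 * np.log(pi)
            ll += norm.logpdf(x[x > 0], mu, sd).sum()
            return -ll

        def fit(x):
            best = None
            for pi0 in (0.3, 0.7):
                r = minimize(negll, [pi0, x[x > 0].mean(), 0.0], args=(x,),
                             method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12,
                                      "maxiter": 5000})
                best = r if best is None or r.fun < best.fun else best
            return -best.fun

        stat_oracle = 2 * (
            fit(x_in) + fit(x_out) - fit(np.concatenate([x_in, x_out]))
        )
        X = np.zeros((80, 2))
        X[:, 0] = np.concatenate([x_in, x_out])
        X[:, 1] = np.abs(rng.normal(1, 0.2, 80))  # second gene, ignored
        e = _expr(np.clip(X, 0, None))
        labels = np.array(["in"] * 40 + ["out"] * 40)
        table = rank_markers_lrt(e, labels)
        row = table[(table["gene"] == "g0") & (table["cluster"] == "in")]
        stat_pkg = chi2.isf(row["p_value"].iloc[0], df=3)
        assert abs(stat_pkg - stat_oracle) < 1e-3 * max(1, stat_oracle)


class TestClusterRelatedness:
    def test_identical_signatures_merge_at_zero(self, rng):
        base = rng.normal(size=30)
        X = np.vstack([base + rng.normal(0, 1e-9, 30) for _ in range(4)]
                      + [rng.normal(size=30)])
        e = _expr(np.clip(X, 0, None) + 0.01)
        labels = np.array(["a", "a2", "b", "b2", "c"])
        Z, names = cluster_relatedness(e, labels)
        assert Z[0, 2] < 1e-6  # first merge: the near-identical pair

    def test_anticorrelated_pair_merges_last(self):
        sig = np.array(
            [[1.0, 2, 3, 4, 5], [1.1, 2, 3, 4, 5.1], [5, 4, 3, 2, 1]]
        )
        e = _expr(sig)
        Z, names = cluster_relatedness(e, np.array(["a", "b", "c"]))
        # final merge height reflects the anti-correlated cluster
        assert Z[-1, 2] > 1.5

    def test_matches_brute_force_average_linkage(self, rng):
        # oracle: direct agglomeration over the 1 - r matrix
        X = rng.normal(size=(5, 20))
        e = _expr(np.clip(X + 3, 0.01, None))
        labels = np.array([f"k{i}" for i in range(5)])
        Z, names = cluster_relatedness(e, labels)

        sig = cluster_signatures(e, labels).to_numpy().T
        D = 1 - np.corrcoef(sig)
        clusters = {i: [i] for i in range(5)}
        merges = []
        nxt = 5
        heights = []
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a < b:
                        d = np.mean([D[i, j] for i in clusters[a]
                                     for j in clusters[b]])
                        if best is None or d < best[0]:
                            best = (d, a, b)
            d, a, b = best
            clusters[nxt] = clusters.pop(a) + clusters.pop(b)
            heights.append(d)
            nxt += 1
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights),
                                   atol=1e-9)

    def test_constant_signature_rejected(self):
        e = _expr(np.ones((4, 10)))
        with pytest.raises(ValueError, match="constant"):
            cluster_relatedness(e, np.array(["a", "a", "b", "b"]))

    def test_newick_rendering_contains_all_leaves(self, rng):
        X = rng.normal(size=(4, 15))
        e = _expr(np.clip(X + 3, 0.01, None))
        labels = np.array(["w", "x", "y", "z"])
        Z, names = cluster_relatedness(e, labels)
        nwk = linkage_to_newick(Z, names)
        assert nwk.endswith(";") and all(n in nwk for n in names)


class TestCellCycle:
    def test_packaged_sets_sizes(self):
        sets = load_mouse_cycle_genes()
        assert len(sets.g1s_genes) == 43
        assert len(sets.g2m_genes) == 54
        assert not set(sets.g1s_genes) & set(sets.g2m_genes)

    def test_uniform_cell_scores_zero_phase_g1(self):
        sets = CycleGeneSets(g1s_genes=["A", "B"], g2m_genes=["C", "D"])
        vals = np.ones((5, 8))
        e = _expr(vals, symbols=["A", "B", "C", "D", "E", "F", "G", "H"])
        out = score_cell_cycle(e, sets, seed=0)
        np.testing.assert_allclose(out["s_score"], 0, atol=1e-12)
        assert (out["phase"] == "G1").all()

    def test_boosted_g2m_called(self, rng):
        sets = load_mouse_cycle_genes()
        m, phases = simulate_cycle_population(
            sets.g1s_genes, sets.g2m_genes, phase_fracs=(0.5, 0.0, 0.5),
            n_cells=200, boost=4.0, seed=1
        )
        out = score_cell_cycle(normalize_log(m), sets, seed=0)
        boosted = out["phase"][phases == "G2M"]
        assert (boosted == "G2M").mean() > 0.9

    def test_planted_phase_fractions_recovered(self):
        sets = load_mouse_cycle_genes()
        m, phases = simulate_cycle_population(
            sets.g1s_genes, sets.g2m_genes, phase_fracs=(0.5, 0.25, 0.25),
            n_cells=900, seed=2
        )
        out = score_cell_cycle(normalize_log(m), sets, seed=0)
        for phase, target in (("G1", 0.5), ("S", 0.25), ("G2M", 0.25)):
            got = (out["phase"] == phase).mean()
            assert abs(got - target) <= 0.05, (phase, got)


class TestCrossCorrelate:
    def test_self_correlation_diagonal_one(self, rng):
        sig = pd.DataFrame(rng.normal(size=(20, 3)),
                           index=[f"g{i}" for i in range(20)],
                           columns=["a", "b", "c"])
        r, best, n = cross_correlate_signatures(sig, sig)
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)
        assert (best == ["a", "b", "c"]).all()

    def test_negation_gives_minus_one(self, rng):
        sig = pd.DataFrame(rng.normal(size=(15, 1)),
                           index=[f"g{i}" for i in range(15)], columns=["a"])
        r, _, _ = cross_correlate_signatures(sig, -sig)
        np.testing.assert_allclose(r.iloc[0, 0], -1.0, atol=1e-12)

    def test_matches_hand_pearson_on_worked_table(self):
        # 5-gene worked example; r computed by the textbook formula
        a = np.array([1.0, 2, 3, 4, 10])
        b = np.array([2.0, 1, 4, 3, 9])
        genes = [f"g{i}" for i in range(5)]
        sa = pd.DataFrame({"a": a}, index=genes)
        sb = pd.DataFrame({"b": b}, index=genes)
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        with pytest.raises(ValueError):
            cross_correlate_signatures(sa, sb)  # < 10 shared genes
        genes10 = [f"g{i}" for i in range(10)]
        a10 = np.concatenate([a, a])
        b10 = np.concatenate([b, b])
        sa = pd.DataFrame({"a": a10}, index=genes10)
        sb = pd.DataFrame({"b": b10}, index=genes10)
        r, _, n = cross_correlate_signatures(sa, sb)
        num = ((a10 - a10.mean()) * (b10 - b10.mean())).sum()
        den = np.sqrt(((a10 - a10.mean()) ** 2).sum()
                      * ((b10 - b10.mean()) ** 2).sum())
        assert n == 10
        np.testing.assert_allclose(r.iloc[0, 0], num / den, atol=1e-12)
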
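"""Bias-corrected Moran's I, program clustering, gene-set scoring, winsorized
normalization, conserved healthy gene groups, explained variance."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import isletkit as ik
from conftest import truth_program_sets


class TestCorrectedMoransI:
    def test_exact_linear_baseline_residuals_zero(self):
        rng = np.random.default_rng(0)
        n_expr = np.unique(rng.integers(10, 5000, 300))
        I = 0.05 + 0.1 * np.log10(n_expr)  # exactly on a line
        cm = ik.corrected_morans_i(I, n_expr, n_bins=10, per_bin=3)
        base = cm.table[cm.table.used_in_baseline]
        assert np.abs(base.corrected_I).max() < 1e-10

    def test_gene_above_trend_positive_residual(self):
        n_expr = np.arange(10, 310)
        I = 0.01 * np.log10(n_expr)
        I[50] += 0.3
        cm = ik.corrected_morans_i(I, n_expr, n_bins=10, per_bin=3)
        assert cm.table.loc[cm.table.index[50], "corrected_I"] > 0.25

    def test_downsampling_bias_removed(self):
        rng = np.random.default_rng(0)
        n, G = 2000, 300
        x = rng.uniform(0, 1, n)
        emb = np.column_stack([x, 0.05 * rng.normal(size=n)])
        graph = ik.knn_graph(emb, k=15)
        lam = np.exp(0.5 + 0.8 * np.sin(2 * np.pi * x))
        q = np.logspace(np.log10(0.02), 0, G)
        counts = rng.poisson(lam[:, None] * q[None, :])
        I = ik.morans_i_genes(np.log1p(counts), graph)
        n_expr = (counts > 0).sum(0)
        ok = n_expr >= 3
        rho_raw = spearmanr(I[ok], n_expr[ok]).statistic
        cm = ik.corrected_morans_i(I[ok], n_expr[ok], high_expr_cutoff=0.9 * n)
        rho_corr = spearmanr(cm.table.corrected_I, cm.table.n_expressed).statistic
        assert rho_raw > 0.3
        assert abs(rho_corr) < 0.1

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        n_expr = rng.integers(5, 1000, 200)
        I = rng.normal(0, 0.1, 200)
        genes = np.array([f"g{i}" for i in range(200)])
        cm1 = ik.corrected_morans_i(I, n_expr, genes=genes)
        perm = rng.permutation(200)
        cm2 = ik.corrected_morans_i(I[perm], n_expr[perm], genes=genes[perm])
        merged = cm1.table.set_index("gene").join(cm2.table.set_index("gene"),
                                                 rsuffix="_p")
        assert np.allclose(merged.corrected_I, merged.corrected_I_p, atol=1e-9)


class TestClusterGenePrograms:
    def test_duplicated_profiles_co_assigned(self):
        prof = np.vstack([np.tile([1.0, 0, 0, 1], (5, 1)),
                          np.tile([0.0, 1, 1, 0], (5, 1))])
        prof = prof + 0.01 * np.arange(4)
        genes = [f"g{i}" for i in range(10)]
        progs = ik.cluster_gene_programs(genes, prof, min_size=2)
        assign = {g: p.id for p in progs for g in p.genes}
        assert len({assign[g] for g in genes[:5]}) == 1
        assert assign[genes[0]] != assign[genes[5]]

    def test_cut_above_max_height_single_program(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=(12, 6))
        progs = ik.cluster_gene_programs([f"g{i}" for i in range(12)], prof,
                                         cut=10.0, min_size=2)
        assert len(progs) == 1 and len(progs[0].genes) == 12

    def test_identical_genes_single_program(self):
        prof = np.tile([1.0, 2, 3], (6, 1))
        progs = ik.cluster_gene_programs([f"g{i}" for i in range(6)], prof, min_size=2)
        assert len(progs) == 1

    def test_planted_programs_recovered(self, healthy_beta):
        from sklearn.metrics import adjusted_rand_score

        prep, truth = healthy_beta
        beta, graph = prep["beta"], prep["graph"]
        n_expr = np.asarray((beta.layers["lognorm"] > 0).sum(axis=0)).ravel()
        cand = np.where(n_expr >= 10)[0]
        I = ik.morans_i_genes(beta.layers["lognorm"][:, cand], graph)
        cm = ik.corrected_morans_i(I, n_expr[cand], genes=beta.var_names[cand].to_numpy(),
                                   high_expr_cutoff=0.40 * beta.n_obs)
        top = cm.top_genes(top_k=200)
        fine = ik.leiden_partition(graph, resolution=20.0, seed=0)
        pb = ik.fine_pseudobulk(beta.layers["lognorm"], fine)
        tidx = [beta.var_names.get_loc(g) for g in top]
        progs = ik.cluster_gene_programs(top, pb.profiles[:, tidx].T)
        pm = truth.program_membership
        pred = {g: p.id for p in progs for g in p.genes}
        genes = list(pm)
        ari = adjusted_rand_score([pm[g] for g in genes],
                                  [pred.get(g, "none") for g in genes])
        assert ari >= 0.8


class TestScoreGeneSet:
    def test_constant_bins_exact_difference(self):
        # 4 set genes constant at 3, control candidates constant at 1; one bin
        X = np.column_stack([np.full((50, 4), 3.0), np.full((50, 8), 1.0)])
        names = [f"g{i}" for i in range(12)]
        s = ik.score_gene_set(X, names, names[:4], n_ctrl_bins=1, seed=0)
        assert np.allclose(s, 3.0 - 1.0)

    def test_null_set_scores_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, (400, 300)).astype(float)
        names = [f"g{i}" for i in range(300)]
        s = ik.score_gene_set(X, names, list(rng.choice(names, 20, replace=False)),
                              seed=1)
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean()) < 3 * se + 1e-3

    def test_seed_reproducibility_and_missing_genes(self):
        rng = np.random.default_rng(2)
        X = rng.random((60, 40))
        names = [f"g{i}" for i in range(40)]
        s1 = ik.score_gene_set(X, names, ["g1", "g2", "not_measured"], seed=9)
        s2 = ik.score_gene_set(X, names, ["g1", "g2"], seed=9)
        assert np.allclose(s1, s2)
        with pytest.raises(ValueError):
            ik.score_gene_set(X, names, ["absent"], seed=0)


class TestMinmaxWinsorized:
    def test_documented_arithmetic(self):
        s = ik.minmax_winsorized(np.arange(100.0), n_trim=20)
        assert s[20] == 0.0 and s[79] == 1.0 and s[0] == 0.0 and s[99] == 1.0
        mid = ik.minmax_winsorized(np.append(np.arange(100.0), 49.5), n_trim=20)
        assert mid[-1] == pytest.approx((49.5 - 20.0) / 59.0, abs=1e-12)

    def test_constant_scores_all_half(self):
        assert np.allclose(ik.minmax_winsorized(np.full(50, 3.3)), 0.5)

    def test_monotone_within_range_and_fallback(self):
        s = np.sort(np.random.default_rng(0).normal(size=200))
        out = ik.minmax_winsorized(s, n_trim=20)
        assert (np.diff(out) >= 0).all()
        with pytest.warns(UserWarning):
            small = ik.minmax_winsorized(np.arange(10.0), n_trim=20)
        assert small.min() == 0.0 and small.max() == 1.0


class TestConservedVariableGeneGroups:
    def _sample(self, rng, planted, n=700, G=400):
        x = rng.uniform(0, 1, n)
        emb = np.column_stack([x, 0.05 * rng.normal(size=n)])
        # sparse background so most genes stay below the 30% baseline cutoff
        X = rng.poisson(0.2, (n, G)).astype(float)
        if planted:
            # one coexpressed smooth module on genes 0..19
            s = np.exp(np.sin(2 * np.pi * x))
            X[:, :20] = rng.poisson(s[:, None] * np.ones(20)[None, :])
        Xl = np.log1p(X)
        graph = ik.knn_graph(emb, k=15)
        labels = (x * 30).astype(int)
        pbm = ik.fine_pseudobulk(Xl, labels)
        return Xl, graph, pbm

    def test_program_in_all_samples_recovered_and_absent_excluded(self):
        rng = np.random.default_rng(4)
        names = np.array([f"g{i}" for i in range(400)])
        expr, graphs, pbs = {}, {}, {}
        for i, planted in enumerate([True, True, True]):
            X, g, p = self._sample(rng, planted)
            expr[f"s{i}"], graphs[f"s{i}"], pbs[f"s{i}"] = X, g, p
        groups = ik.conserved_variable_gene_groups(expr, graphs, pbs, names,
                                                   top_k=60, min_size=5, cut=0.5)
        planted_genes = set(names[:20])
        best = max(groups, key=lambda gr: len(set(gr.genes) & planted_genes))
        assert len(set(best.genes) & planted_genes) / 20 >= 0.8

        # plant the module in only one of three samples -> excluded
        expr2, graphs2, pbs2 = {}, {}, {}
        for i, planted in enumerate([True, False, False]):
            X, g, p = self._sample(rng, planted)
            expr2[f"s{i}"], graphs2[f"s{i}"], pbs2[f"s{i}"] = X, g, p
        groups2 = ik.conserved_variable_gene_groups(expr2, graphs2, pbs2, names,
                                                    top_k=60, min_size=5, cut=0.5)
        recovered = set().union(*[set(g.genes) for g in groups2]) if groups2 else set()
        assert len(recovered & planted_genes) / 20 < 0.5


class TestExplainedVariance:
    def test_single_gp_equal_to_pc1_returns_its_varratio(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 40)) @ np.diag(np.linspace(3, 0.5, 40))
        pca = PCA(n_components=10).fit(X - X.mean(0))
        pc_scores = pca.transform(X - X.mean(0))
        gp = ik.GeneProgram(id="gp0", genes=["g0"], score=pc_scores[:, 0])
        names = np.array([f"g{i}" for i in range(40)])
        ev = ik.explained_variance(X, names, [gp], n_pcs=10, n_rand=0, seed=0)
        assert ev["total_ev"] == pytest.approx(pca.explained_variance_ratio_[0], abs=1e-8)

    def test_ev_bounded(self, healthy_beta):
        prep, truth = healthy_beta
        beta = prep["beta"]
        sets = truth_program_sets(truth)
        gps = [ik.GeneProgram(id=k, genes=v) for k, v in sets.items()]
        ev = ik.explained_variance(beta.layers["lognorm"], beta.var_names.to_numpy(),
                                   gps, hvgs=prep["hvgs"][:500], n_pcs=20, n_rand=5,
                                   seed=0)
        assert 0.0 <= ev["total_ev"] <= ev["varratio"].sum() + 1e-12
        assert ev["empirical_p"] <= 1.0


def test_program_stability_under_subsampling(healthy_beta):
    """Programs recovered from an 80% cell subsample share most genes."""
    prep, truth = healthy_beta
    beta, graph = prep["beta"], prep["graph"]

    def discover(b, g):
        n_expr = np.asarray((b.layers["lognorm"] > 0).sum(axis=0)).ravel()
        cand = np.where(n_expr >= 10)[0]
        I = ik.morans_i_genes(b.layers["lognorm"][:, cand], g)
        cm = ik.corrected_morans_i(I, n_expr[cand], genes=b.var_names[cand].to_numpy(),
                                   high_expr_cutoff=0.40 * b.n_obs)
        top = cm.top_genes(top_k=200)
        fine = ik.leiden_partition(g, resolution=20.0, seed=0)
        pb = ik.fine_pseudobulk(b.layers["lognorm"], fine)
        tidx = [b.var_names.get_loc(x) for x in top]
        return ik.cluster_gene_programs(top, pb.profiles[:, tidx].T)

    full = discover(beta, graph)
    rng = np.random.default_rng(0)
    sub_idx = np.sort(rng.choice(beta.n_obs, int(0.8 * beta.n_obs), replace=False))
    bsub = beta[sub_idx].copy()
    sub = discover(bsub, ik.knn_graph(prep["latent"][sub_idx], k=15))

    def best_jaccard(p, others):
        return max(len(set(p.genes) & set(q.genes)) / len(set(p.genes) | set(q.genes))
                   for q in others)

    jacc = [best_jaccard(p, sub) for p in full if len(p.genes) >= 10]
    assert np.mean(jacc) >= 0.6
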
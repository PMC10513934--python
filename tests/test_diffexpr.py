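"""Statistical oracles (Welch, BH, Mann-Whitney, hypergeometric), the NB-GLM,
and the cross-dataset selection rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import isletkit as ik
from isletkit.diffexpr import signed_min_lfc


def bh_step_up_oracle(p):
    """Hand-rolled BH step-up recursion."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestWelch:
    def test_closed_form_example(self):
        t, df, p = ik.welch_t([1, 2, 3], [3, 4, 5])
        assert t == pytest.approx(-2.449, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-3)

    def test_identical_groups(self):
        t, df, p = ik.welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, _, p1 = ik.welch_t([1, 2, 4], [5, 6, 9])
        t2, _, p2 = ik.welch_t([5, 6, 9], [1, 2, 4])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            ik.welch_t([1.0], [2.0, 3.0])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        ps = [ik.welch_t(rng.normal(size=20), rng.normal(size=25))[2]
              for _ in range(5000)]
        assert st.kstest(ps, "uniform").pvalue > 0.01


class TestBH:
    def test_worked_example(self):
        adj = ik.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_and_saturated(self):
        assert ik.bh_fdr([0.2]).tolist() == [0.2]
        assert np.allclose(ik.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(ik.bh_fdr(p), bh_step_up_oracle(p), atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ik.bh_fdr([0.1, np.nan])


class TestScoreCompare:
    def test_exact_disjoint_groups(self):
        U, p, eff = ik.score_compare([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_median_ratio_effect(self):
        _, _, eff = ik.score_compare([2.0, 2, 2], [1.0, 1, 1])
        assert eff == pytest.approx(np.log(2.0))

    def test_identical_groups_p_one(self):
        _, p, _ = ik.score_compare([1.0, 2, 3], [1.0, 2, 3])
        assert p == pytest.approx(1.0)

    def test_nonpositive_median_flagged(self):
        _, _, eff = ik.score_compare([-1.0, 0, 1], [1.0, 2, 3])
        assert np.isnan(eff)


class TestHypergeom:
    def test_full_overlap_combinatorial_value(self):
        background = [f"g{i}" for i in range(20)]
        sets = {"s": background[:5]}
        tab = ik.hypergeom_enrichment(background[:5], sets, background, min_size=2)
        assert tab.p[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_one(self):
        background = [f"g{i}" for i in range(30)]
        tab = ik.hypergeom_enrichment(background[:5], {"s": background[20:30]},
                                      background, min_size=2)
        assert tab.p[0] == pytest.approx(1.0)

    def test_size_filter(self):
        background = [f"g{i}" for i in range(1000)]
        sets = {"big": background[:600], "small": background[:3], "ok": background[:10]}
        tab = ik.hypergeom_enrichment(background[:10], sets, background)
        assert tab.gene_set.tolist() == ["ok"]

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            ik.hypergeom_enrichment(["a"], {"s": ["a"]}, [])


class TestSignedMinLfc:
    def test_sign_conflict_reports_zero(self):
        assert signed_min_lfc([0.5, -0.2]) == 0.0

    def test_consistent_signs_report_min_abs(self):
        assert signed_min_lfc([2.0, 0.7, 1.5]) == 0.7
        assert signed_min_lfc([-2.0, -0.7]) == -0.7


class TestNbGlm:
    def test_offset_doubling_leaves_slope_unchanged(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        design = np.column_stack([np.ones(n), x])
        sf = np.exp(rng.normal(0, 0.2, n))
        y = rng.poisson(np.exp(1.0 + 0.5 * x) * sf)
        r1 = ik.nb_glm_wald(y, design, np.log(sf))
        r2 = ik.nb_glm_wald(y, design, np.log(2 * sf))
        assert r1.lfc == pytest.approx(r2.lfc, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-10)

    def test_all_zero_gene_flagged(self):
        r = ik.nb_glm_wald(np.zeros(50), np.column_stack([np.ones(50), np.arange(50)]),
                           np.zeros(50))
        assert "all-zero" in r.flags and r.p == 1.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        n, G = 250, 400
        sf = np.exp(rng.normal(0, 0.3, n))
        x = rng.normal(0, 1, n)
        design = np.column_stack([np.ones(n), x])
        mu0 = rng.uniform(0.5, 20, G)
        lam = mu0[None, :] * sf[:, None] * rng.gamma(1 / 0.3, 0.3, (n, G))
        tab = ik.nb_glm_table(rng.poisson(lam), design, np.log(sf))
        clean = tab[tab["flags"] == ""]
        rate = (clean.p < 0.05).mean()
        assert 0.02 <= rate <= 0.08  # looser band than acceptance (smaller sim)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(3)
        n, G = 600, 40
        x = rng.uniform(0, 1, n)
        sf = np.exp(rng.normal(0, 0.3, n))
        design = np.column_stack([np.ones(n), x])
        mu = np.exp(np.log(rng.uniform(2, 10, G))[None, :] + 1.0 * x[:, None]) * sf[:, None]
        tab = ik.nb_glm_table(rng.poisson(mu * rng.gamma(1 / 0.3, 0.3, (n, G))),
                              design, np.log(sf))
        assert (tab.lfc * np.log(2)).mean() == pytest.approx(1.0, abs=0.15)


@pytest.fixture(scope="module")
def dge_run(diseased_atlas):
    cfg, adata, truth = diseased_atlas
    m = ((adata.obs.true_cell_type == "beta").to_numpy()
         & ~adata.obs.is_doublet.to_numpy() & ~adata.obs.is_empty.to_numpy())
    sub = adata[m].copy()
    sub = ik.normalize_log1p(sub)
    tab = ik.trajectory_dge(
        sub.X, sub.var_names.to_numpy(),
        process=sub.obs.true_disease_process.to_numpy(),
        size_factors=sub.obs.size_factor.to_numpy(),
        condition=sub.obs.condition.to_numpy(),
        dataset_labels=sub.obs.dataset.to_numpy())
    return truth, tab


class TestTrajectoryDge:
    def test_planted_process_genes_recovered(self, dge_run):
        truth, tab = dge_run
        planted = set(truth.process_genes["up"]) | set(truth.process_genes["down"])
        hits = set(tab.loc[tab.is_deg, "gene"])
        sensitivity = len(hits & planted) / len(planted)
        assert sensitivity >= 0.8
        # false discoveries among genes with no planted process response
        null_genes = set(tab.gene) - planted - set(truth.program_membership) \
            - {g for gs in truth.marker_genes.values() for g in gs}
        null_hits = hits & null_genes
        assert len(null_hits) / max(len(hits), 1) <= 0.35  # markers/programs co-move

    def test_low_expression_filter(self):
        # gene 1 expressed in 2% of both condition groups -> never tested
        rng = np.random.default_rng(0)
        n = 400
        counts = rng.poisson(3.0, (n, 3))
        counts[:, 1] = 0
        rare = rng.choice(n, 8, replace=False)
        counts[rare, 1] = 5
        cond = np.where(np.arange(n) < 200, "healthy", "diseased")
        tab = ik.trajectory_dge(counts, np.array(["a", "b", "c"]),
                                process=rng.uniform(0, 1, n),
                                size_factors=np.ones(n), condition=cond)
        row = tab[tab.gene == "b"].iloc[0]
        assert not row.tested and row["flags"] == "low-expression" and not row.is_deg
        assert tab[tab.gene != "b"].tested.all()


class TestConservedStateMarkers:
    def test_planted_markers_recovered(self, healthy_beta):
        prep, truth = healthy_beta
        beta = prep["beta"]
        rep = ik.conserved_state_markers(
            beta.layers["lognorm"], beta.var_names.to_numpy(),
            beta.obs.true_state.to_numpy(), beta.obs.dataset.to_numpy(),
            beta.obs["sample"].to_numpy())
        truth_pairs = {(g, s) for s, gs in truth.marker_genes.items() for g in gs}
        found = set(zip(rep.gene, rep.state))
        assert len(found & truth_pairs) / len(truth_pairs) >= 0.8
        assert len(found & truth_pairs) / max(len(found), 1) >= 0.8

    def test_relative_expression_filter(self, healthy_beta):
        prep, truth = healthy_beta
        beta = prep["beta"]
        rel = pd.Series(1.0, index=beta.var_names)
        some_marker = truth.marker_genes["state0"][0]
        rel[some_marker] = 0.1
        rep = ik.conserved_state_markers(
            beta.layers["lognorm"], beta.var_names.to_numpy(),
            beta.obs.true_state.to_numpy(), beta.obs.dataset.to_numpy(),
            beta.obs["sample"].to_numpy(), rel_expr=rel.to_numpy())
        assert some_marker not in set(rep.gene)


class TestPairwiseCelltypeMarkers:
    def test_planted_type_markers(self, small_atlas):
        _, adata, truth = small_atlas
        keep = (~adata.obs.is_empty.to_numpy()) & (~adata.obs.is_doublet.to_numpy())
        sub = adata[keep]
        keys = sub.obs[["true_cell_type", "sample", "sex"]].rename(
            columns={"true_cell_type": "cell_type"})
        pbm = ik.metadata_pseudobulk(sub.X, keys)
        rep = ik.pairwise_celltype_markers(pbm, gene_names=sub.var_names.to_numpy())
        for ct, genes in truth.type_marker_genes.items():
            called = set(rep.loc[rep.cell_type == ct, "gene"])
            assert len(called & set(genes)) / len(genes) >= 0.8
        # a marker belongs to exactly one cell type
        assert rep.groupby("gene")["cell_type"].nunique().max() == 1


class TestConservedConditionGenes:
    def _tab(self, rows):
        return pd.DataFrame(rows, columns=["gene", "fdr", "lfc", "tested"])

    def test_half_rule(self):
        per_ds = {
            f"d{i}": self._tab([("gA", 0.01, 1.0, True), ("gB", 0.01, 1.0, i < 1),
                                ("gC", 0.9, 1.0, True)])
            for i in range(4)
        }
        # gA passes everywhere; gB only tested (and passing) in 1/4; gC never significant
        out = ik.conserved_condition_genes(per_ds)
        assert out == ["gA"]

    def test_two_of_four_selected(self):
        per_ds = {}
        for i in range(4):
            fdr = 0.01 if i < 2 else 0.9
            per_ds[f"d{i}"] = self._tab([("g", fdr, 1.0, True)])
        assert ik.conserved_condition_genes(per_ds) == ["g"]
        per_ds["d1"] = self._tab([("g", 0.9, 1.0, True)])
        assert ik.conserved_condition_genes(per_ds) == []


class TestMarkerTranslation:
    def test_translation_requires_all_datasets(self):
        rng = np.random.default_rng(0)
        n = 60
        mask = np.arange(n) < 30
        X_up = np.column_stack([np.where(mask, 5.0, 1.0) + rng.normal(0, 0.2, n)])
        X_flat = np.column_stack([np.ones(n) + rng.normal(0, 0.2, n)])
        out = ik.marker_translation_test(
            {"d1": X_up, "d2": X_up}, {"d1": mask, "d2": mask}, ["m"], ["m"])
        assert out.translates.all()
        out2 = ik.marker_translation_test(
            {"d1": X_up, "d2": X_flat}, {"d1": mask, "d2": mask}, ["m"], ["m"])
        assert not out2.translates.any()

    def test_planted_cross_dataset_marker(self, healthy_beta):
        prep, truth = healthy_beta
        beta = prep["beta"]
        marker = truth.marker_genes["state1"][0]
        expr, masks = {}, {}
        for d in pd.unique(beta.obs.dataset):
            sel = (beta.obs.dataset == d).to_numpy()
            expr[d] = beta.layers["lognorm"][sel]
            masks[d] = (beta.obs.true_state.to_numpy()[sel] == "state1")
        out = ik.marker_translation_test(expr, masks, [marker],
                                         beta.var_names.to_numpy())
        assert out.translates.all()


class TestClusterDegGroups:
    def test_two_mechanisms_recovered_and_scores_bounded(self):
        rng = np.random.default_rng(0)
        n_pb = 30
        profA = np.sin(np.linspace(0, 3, n_pb))
        profB = np.cos(np.linspace(0, 3, n_pb))
        genes = [f"g{i}" for i in range(20)]
        profiles = np.column_stack(
            [profA + 0.05 * rng.normal(size=n_pb) for _ in range(10)]
            + [profB + 0.05 * rng.normal(size=n_pb) for _ in range(10)])
        deg = pd.DataFrame({"gene": genes, "lfc": [1.5] * 20, "is_deg": True})
        X = rng.random((100, 20))
        groups = ik.cluster_deg_groups(deg, profiles, np.array(genes),
                                       norm_expr=X, min_size=3, n_trim=5)
        up = groups["up"]
        assert len(up) == 2
        members = [set(g["genes"]) for g in up]
        assert set(genes[:10]) in members and set(genes[10:]) in members
        for g in up:
            assert g["score"].min() >= 0.0 and g["score"].max() <= 1.0
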
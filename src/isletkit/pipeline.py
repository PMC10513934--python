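"""End-to-end pipeline driver: simulate/read -> qc -> normalize -> ambient ->
embedding graph + conservation -> gene programs -> states -> trajectory ->
differential expression -> enrichment.

All stage outputs are TSVs stamped with a provenance header (stage name,
parameters, config hash, seed); all randomness flows from one seed via named
substreams, so two runs with the same config are byte-identical apart from
nothing (no timestamps are written).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import ambient as amb
from . import diffexpr as dge
from . import graph as gr
from . import io as iio
from . import preprocess as pp
from . import programs as gp
from . import pseudobulk as pb
from . import synthetic as syn
from . import trajectory as traj
from ._utils import substream, write_tsv

_KNOWN_KEYS = {
    "seed", "out_dir", "input_path", "simulate", "qc", "normalize", "ambient",
    "graph", "programs", "states", "trajectory", "dge", "enrich",
}


def load_config(path) -> dict:
    import tomllib
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    if "input_path" in cfg and not os.path.exists(cfg["input_path"]):
        raise FileNotFoundError(f"input_path does not exist: {cfg['input_path']}")
    return cfg


def default_config(seed: int = 0, out_dir: str = "isletkit_out") -> dict:
    return {"seed": seed, "out_dir": out_dir, "simulate": {}}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err!r}")
        self.stage = stage


def _pca_embedding(adata, hvgs, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA
    idx = [adata.var_names.get_loc(h) for h in hvgs]
    X = np.asarray(adata.layers["lognorm"][:, idx].todense())
    X -= X.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    return PCA(n_components=n_pcs, random_state=seed % (2**31),
               svd_solver="full").fit_transform(X)


def run_pipeline(config: dict, return_data: bool = False) -> dict:
    """Execute every stage on the configured (or simulated) dataset.

    Returns a report dict with per-stage summary numbers; writes one TSV per
    stage plus a JSON report under ``out_dir``.
    """
    cfg = validate_config(dict(config))
    seed = int(cfg.get("seed", 0))
    out_dir = cfg.get("out_dir")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    report: dict = {"seed": seed}
    prov = {"seed": seed}

    def emit(name, df, stage, params=None):
        if out_dir:
            write_tsv(df, os.path.join(out_dir, name), stage, {**prov, **(params or {})})

    # ---- stage: data -------------------------------------------------------
    stage = "data"
    try:
        if "input_path" in cfg:
            adata = iio.read_expression(cfg["input_path"])
            truth = None
            tj = os.path.join(str(cfg["input_path"]), "truth.json")
            if os.path.exists(tj):
                truth = syn.GroundTruth.from_json(open(tj).read())
        else:
            sim_kwargs = dict(cfg.get("simulate", {}))
            sim_kwargs.setdefault("seed", seed)
            if "program_size_range" in sim_kwargs:
                sim_kwargs["program_size_range"] = tuple(sim_kwargs["program_size_range"])
            scfg = syn.SyntheticConfig(**sim_kwargs)
            adata, truth = syn.generate_atlas(scfg)
        report["n_droplets"] = int(adata.n_obs)
        report["n_genes"] = int(adata.n_vars)
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: ambient profiles (raw, needs near-empty droplets) ----------
    stage = "ambient"
    try:
        acfg = cfg.get("ambient", {})
        profiles = [
            amb.ambient_profile(adata.X[(adata.obs["sample"] == s).to_numpy()],
                                sample=s, max_count=acfg.get("max_count", 100))
            for s in pd.unique(adata.obs["sample"])
        ]
        small_idx, large_idx = amb.top_ambient_genes(
            profiles, small_target=acfg.get("small_target", 20),
            large_target=acfg.get("large_target", 100))
        small_set = [adata.var_names[i] for i in small_idx]
        large_set = [adata.var_names[i] for i in large_idx]
        report["n_ambient_small"] = len(small_set)
        report["n_ambient_large"] = len(large_set)
        amb_tab = pd.DataFrame({"gene": large_set,
                                "in_small_set": [g in set(small_set) for g in large_set]})
        for prof in profiles:
            amb_tab[f"proportion_{prof.sample}"] = prof.gene_proportion[large_idx]
        emit("ambient_genes.tsv", amb_tab, stage, acfg)
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: qc ---------------------------------------------------------
    stage = "qc"
    try:
        qcfg = cfg.get("qc", {})
        thr = pp.QCThresholds(
            min_genes=qcfg.get("min_genes", 100),
            min_counts=qcfg.get("min_counts", 200),
            max_counts=qcfg.get("max_counts", np.inf),
            max_mito_frac=qcfg.get("max_mito_frac", 1.0),
        )
        adata, qc_report = pp.filter_cells(adata, thr)
        report["n_cells_qc"] = int(adata.n_obs)
        emit("qc_report.tsv", qc_report, stage, qcfg)
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: normalize --------------------------------------------------
    stage = "normalize"
    try:
        ncfg = cfg.get("normalize", {})
        adata = pp.normalize_log1p(adata, method=ncfg.get("method", "total"))
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: graph / embedding conservation -----------------------------
    stage = "graph"
    try:
        gcfg = cfg.get("graph", {})
        n_hvg = gcfg.get("n_hvg", 2000)
        k = gcfg.get("k", 15)
        hvgs = pp.hvg_batch(adata, n_top=min(n_hvg, adata.n_vars), batch_key="sample")
        embedding = _pca_embedding(adata, hvgs, gcfg.get("n_pcs", 15), seed)
        cons = gr.conservation_score(adata, embedding, batch_key="sample",
                                     g=min(gcfg.get("g", 1000), adata.n_vars), k=k)
        graph_all = gr.knn_graph(embedding, k=k)
        report["conservation_score"] = float(cons.score)
        report["conservation_mean_I"] = float(cons.mean_I)
        emit("conservation.tsv",
             pd.DataFrame({"gene": cons.genes, "morans_i": cons.per_gene_I}),
             stage, gcfg)
    except Exception as e:
        raise StageError(stage, e)

    # ---- relative expression + non-beta ambient genes ----------------------
    stage = "ambient-relative"
    try:
        ct_col = ("cell_type" if "cell_type" in adata.obs
                  else "true_cell_type" if "true_cell_type" in adata.obs else None)
        rel_beta = None
        non_beta_ambient: list = []
        if ct_col is not None:
            # known doublets are excluded from the fine clusters so that mixed
            # profiles do not inflate a type's apparent relative expression
            sub = (~adata.obs["is_doublet"].to_numpy().astype(bool)
                   if "is_doublet" in adata.obs else np.ones(adata.n_obs, bool))
            idx_sub = np.where(sub)[0]
            fine2 = pb.leiden_partition(gr.knn_graph(embedding[idx_sub], k=k),
                                        resolution=2.0, seed=seed)
            # relative expression on the linear normalized scale
            lin = adata.layers["lognorm"][idx_sub].copy()
            lin.data = np.expm1(lin.data)
            rel = amb.relative_expression(lin, fine2,
                                          cell_types=adata.obs[ct_col].to_numpy()[idx_sub])
            if syn.BETA_TYPE in rel.columns:
                rel_beta = rel[syn.BETA_TYPE].to_numpy()
                amb_idx = [adata.var_names.get_loc(g) for g in large_set]
                prof = amb.cluster_relative_profiles(lin[:, amb_idx], fine2)
                flagged = amb.non_celltype_ambient_genes(
                    list(range(len(large_set))), prof, rel_beta[amb_idx],
                    cutoff=cfg.get("ambient", {}).get("non_celltype_cutoff", 0.5))
                non_beta_ambient = [large_set[i] for i in flagged]
        report["n_non_beta_ambient"] = len(non_beta_ambient)
    except Exception as e:
        raise StageError(stage, e)

    # ---- beta-cell subset --------------------------------------------------
    stage = "beta-subset"
    try:
        if ct_col is None:
            raise ValueError("no cell-type annotation available")
        beta_mask = (adata.obs[ct_col] == syn.BETA_TYPE).to_numpy()
        if "is_doublet" in adata.obs:
            beta_mask &= ~adata.obs["is_doublet"].to_numpy().astype(bool)
        beta = adata[beta_mask].copy()
        pcfg = cfg.get("programs", {})
        beta_hvgs = pp.hvg_batch(beta, n_top=min(pcfg.get("n_hvg", 2000), beta.n_vars),
                                 batch_key="sample")
        # an integrated embedding (precomputed, or the simulator's latent) is
        # used when available; PCA on HVGs is the unintegrated fallback
        emb_source = pcfg.get("embedding", "auto")
        if emb_source == "auto" and "X_latent" in beta.obsm:
            beta_emb = np.asarray(beta.obsm["X_latent"], dtype=float)
        else:
            beta_emb = _pca_embedding(beta, beta_hvgs, pcfg.get("n_pcs", 15), seed + 1)
        beta_graph = gr.knn_graph(beta_emb, k=cfg.get("graph", {}).get("k", 15))
        report["n_beta_cells"] = int(beta.n_obs)
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: programs ---------------------------------------------------
    stage = "programs"
    try:
        min_cells = pcfg.get("min_cells_expressed", max(10, int(0.01 * beta.n_obs)))
        n_expr = np.asarray((beta.layers["lognorm"] > 0).sum(axis=0)).ravel()
        excluded = set(non_beta_ambient)
        candidate = (n_expr >= min_cells) & ~beta.var_names.isin(sorted(excluded))
        cand_idx = np.where(candidate)[0]
        I = gr.morans_i_genes(beta.layers["lognorm"][:, cand_idx], beta_graph)
        cm = gp.corrected_morans_i(
            I, n_expr[cand_idx], genes=beta.var_names[cand_idx].to_numpy(),
            high_expr_cutoff=pcfg.get("high_expr_frac", 0.40) * beta.n_obs)
        top = cm.top_genes(top_k=pcfg.get("top_k", 200))

        fine_labels = pb.leiden_partition(beta_graph,
                                          resolution=cfg.get("states", {}).get("fine_resolution", 20.0),
                                          seed=seed)
        fine_pb = pb.fine_pseudobulk(beta.layers["lognorm"], fine_labels)
        tidx = [beta.var_names.get_loc(g) for g in top]
        programs = gp.cluster_gene_programs(top, fine_pb.profiles[:, tidx].T,
                                            cut=pcfg.get("cut", None),
                                            min_size=pcfg.get("min_size", 5))
        rng_scores = substream(seed, "gp-scores")
        for p in programs:
            p.score = gp.score_gene_set(beta.layers["lognorm"], beta.var_names.to_numpy(),
                                        p.genes, seed=int(rng_scores.integers(2**31)))
        report["n_programs"] = len(programs)
        report["program_sizes"] = [len(p.genes) for p in programs]
        emit("corrected_morans_i.tsv", cm.table, stage, pcfg)
        if out_dir:
            iio.write_gmt({p.id: p.genes for p in programs},
                          os.path.join(out_dir, "gene_programs.gmt"))

        ev = gp.explained_variance(beta.layers["lognorm"], beta.var_names.to_numpy(),
                                   programs, hvgs=beta_hvgs,
                                   n_pcs=pcfg.get("ev_n_pcs", 30),
                                   n_rand=pcfg.get("ev_n_rand", 20), seed=seed)
        report["programs_total_ev"] = float(ev["total_ev"])
        report["programs_ev_empirical_p"] = float(ev["empirical_p"])
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: states -----------------------------------------------------
    stage = "states"
    try:
        scfg = cfg.get("states", {})
        gp_score_mat = np.column_stack([p.score for p in programs]) if programs else \
            np.zeros((beta.n_obs, 1))
        pb_scores = np.vstack([
            gp_score_mat[fine_pb.cell_to_cluster == c].mean(axis=0)
            for c in fine_pb.keys["cluster"]
        ])
        part = pb.gp_state_clustering(pb_scores, fine_pb,
                                      linkage_cut=scfg.get("linkage_cut", None))
        conn = pb.cluster_connectivity(beta_graph, part.labels,
                                       prune_threshold=scfg.get("prune_threshold", 0.05))
        report["n_fine_states"] = int(len(np.unique(part.labels)))

        cond = beta.obs["condition"].to_numpy()
        purities = []
        for s in np.unique(part.labels):
            m = part.labels == s
            frac = pd.Series(cond[m]).value_counts(normalize=True).iloc[0]
            purities.append(float(frac))
        report["state_condition_purity"] = purities
        report["frac_states_pure"] = float(np.mean([p >= 0.8 for p in purities]))
        emit("states.tsv", pd.DataFrame({
            "cell": beta.obs_names, "fine_state": part.labels,
            "fine_pseudobulk": fine_pb.cell_to_cluster}), stage, scfg)
        emit("state_connectivity.tsv", conn.reset_index(), stage, scfg)
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: trajectory -------------------------------------------------
    stage = "trajectory"
    try:
        tcfg = cfg.get("trajectory", {})
        ps = traj.process_score(beta_graph, beta.obs["condition"].to_numpy(),
                                dataset_labels=beta.obs["dataset"].to_numpy(),
                                t_steps=tcfg.get("t_steps", 3))
        report["process_score_mean_healthy"] = float(
            ps.score[beta.obs["condition"].to_numpy() == "healthy"].mean())
        report["process_score_mean_diseased"] = float(
            ps.score[beta.obs["condition"].to_numpy() == "diseased"].mean())
        if truth is not None:
            tproc = beta.obs["true_disease_process"].to_numpy()
            from scipy.stats import spearmanr
            rho = spearmanr(ps.score, tproc).statistic
            report["process_truth_spearman"] = float(abs(rho))
        emit("process_score.tsv", pd.DataFrame({
            "cell": beta.obs_names, "process_score": ps.score}), stage, tcfg)
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: dge --------------------------------------------------------
    stage = "dge"
    try:
        dcfg = cfg.get("dge", {})
        deg_tab = dge.trajectory_dge(
            beta.X, beta.var_names.to_numpy(),
            process=1.0 - ps.score,  # 0 = healthy end, increases toward disease
            size_factors=beta.obs["size_factor"].to_numpy(),
            condition=beta.obs["condition"].to_numpy(),
            dataset_labels=beta.obs["dataset"].to_numpy(),
            rel_expr=rel_beta,
            fdr=dcfg.get("fdr", 0.05), min_abs_lfc=dcfg.get("min_abs_lfc", 1.0),
            rel_expr_min=dcfg.get("rel_expr_min", 0.2))
        report["n_deg"] = int(deg_tab["is_deg"].sum())
        emit("trajectory_dge.tsv", deg_tab, stage, dcfg)
        groups = dge.cluster_deg_groups(deg_tab, fine_pb.profiles,
                                        beta.var_names.to_numpy(),
                                        norm_expr=beta.layers["lognorm"], seed=seed)
        report["n_deg_groups_up"] = len(groups.get("up", []))
        report["n_deg_groups_down"] = len(groups.get("down", []))
    except Exception as e:
        raise StageError(stage, e)

    # ---- stage: enrich -----------------------------------------------------
    stage = "enrich"
    try:
        ecfg = cfg.get("enrich", {})
        gmt_path = ecfg.get("gmt")
        gene_sets = iio.read_gmt(gmt_path) if gmt_path else (
            {p.id: p.genes for p in programs})
        degs = deg_tab.loc[deg_tab["is_deg"], "gene"].tolist()
        background = deg_tab.loc[deg_tab["tested"], "gene"].tolist()
        if degs and gene_sets:
            enr = dge.hypergeom_enrichment(degs, gene_sets, background,
                                           fdr=ecfg.get("fdr", 0.25))
            report["n_enriched_sets"] = int(enr["significant"].sum()) if len(enr) else 0
            emit("enrichment.tsv", enr, stage, ecfg)
        else:
            report["n_enriched_sets"] = 0
    except Exception as e:
        raise StageError(stage, e)

    if out_dir:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    if return_data:
        report["_data"] = {"adata": adata, "beta": beta, "truth": truth,
                           "programs": programs, "states": part, "process": ps,
                           "deg_table": deg_tab, "fine_pb": fine_pb}
    return report
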
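"""Differential expression machinery: Welch tests, BH FDR, negative-binomial
GLM Wald tests with size-factor offsets, conserved cross-dataset marker rules,
DEG grouping and scoring, hypergeometric gene-set enrichment, Mann-Whitney
gene-set score comparisons, and marker translation tests.

The NB-GLM (log link, size factors as exposure offset, per-gene dispersion by
method of moments on Pearson residuals, two-sided Wald test on the coefficient
of interest, log2-reported fold changes) is the single count-model core behind
the trajectory, sex-difference and pseudobulk cell-type-marker analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
SE_DEGENERATE = 1e-12


@dataclass
class DGEResult:
    gene: object
    contrast: str
    stat: float
    p: float
    fdr: float = np.nan
    lfc: float = np.nan
    flags: list = field(default_factory=list)


@dataclass
class MarkerReport:
    gene: object
    state: object
    max_fdr: float
    signed_min_lfc: float


# ---------------------------------------------------------------------------
# elementary statistics

def welch_t(a, b) -> tuple[float, float, float]:
    """Two-sided Welch's t-test; returns (t, Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va = max(a.var(ddof=1), SE_DEGENERATE)
    vb = max(b.var(ddof=1), SE_DEGENERATE)
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.size**2 * (a.size - 1)) + vb**2 / (b.size**2 * (b.size - 1)))
    p = 2.0 * st.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def score_compare(scores_a, scores_b, exact_max_n: int = 8):
    """Two-sided Mann-Whitney U between per-cell gene-set scores.

    Returns (U, p, effect) with effect = ln(median_a / median_b); callers pass
    the diseased group as ``a`` and healthy as ``b`` per the sign convention.
    A non-positive median makes the ratio undefined (effect = NaN).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    method = "exact" if max(a.size, b.size) <= exact_max_n else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = np.median(a), np.median(b)
    effect = np.log(med_a / med_b) if med_a > 0 and med_b > 0 else np.nan
    return float(res.statistic), float(res.pvalue), float(effect)


def hypergeom_enrichment(query_genes, gene_sets: dict, background,
                         fdr: float = 0.25, min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query_genes`` in each set.

    Sets are intersected with the background and size-filtered before testing;
    BH adjustment runs across the retained sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes) & background
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & background
        if len(gs) < min_size or len(gs) > max_size:
            continue
        overlap = len(query & gs)
        M, K, n = len(background), len(gs), len(query)
        p = float(st.hypergeom.sf(overlap - 1, M, K, n))
        rows.append({"gene_set": name, "set_size": K, "overlap": overlap, "p": min(p, 1.0)})
    tab = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if len(tab):
        tab["fdr"] = bh_fdr(tab["p"].to_numpy())
        tab["significant"] = tab["fdr"] < fdr
        tab = tab.sort_values(["p", "gene_set"]).reset_index(drop=True)
    return tab


# ---------------------------------------------------------------------------
# NB GLM core

def _mom_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments NB dispersion alpha from Pearson-style residuals."""
    num = float(((y - mu) ** 2 - mu).sum())
    den = float((mu**2).sum())
    alpha = num / den if den > 0 else 0.0
    return max(alpha, 1e-8)


def nb_glm_wald(counts_gene, design: np.ndarray, offset_log_sf: np.ndarray,
                test_coef: int = 1, gene=None, n_disp_iter: int = 2,
                contrast: np.ndarray | None = None) -> DGEResult:
    """Wald test on one coefficient (or contrast) of a negative-binomial GLM.

    Fits ``counts ~ NB(exp(design @ beta + offset))`` by IRLS: a Poisson fit
    initializes the mean, dispersion is re-estimated by method of moments on the
    residuals, and the NB fit/dispersion loop runs ``n_disp_iter`` times. The
    reported lfc is the tested coefficient divided by ln 2 (log2 scale).
    Degenerate fits (SE below 1e-12, non-convergence, all-zero gene) are
    flagged with p = 1 so they can be excluded downstream.
    """
    y = np.asarray(counts_gene, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    offset = np.asarray(offset_log_sf, dtype=float).ravel()
    name = gene if gene is not None else ""
    label = f"coef{test_coef}"

    if y.sum() == 0:
        return DGEResult(gene=name, contrast=label, stat=0.0, p=1.0, lfc=0.0,
                         flags=["all-zero"])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(maxiter=50)
            mu = pois.mu
            alpha = _mom_dispersion(y, mu, X.shape[1])
            res = pois
            for _ in range(n_disp_iter):
                res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                             offset=offset).fit(maxiter=50)
                alpha = _mom_dispersion(y, res.mu, X.shape[1])
    except Exception:
        return DGEResult(gene=name, contrast=label, stat=0.0, p=1.0, lfc=0.0,
                         flags=["degenerate-fit"])

    if contrast is not None:
        c = np.asarray(contrast, dtype=float)
        est = float(c @ res.params)
        se = float(np.sqrt(c @ res.cov_params() @ c))
    else:
        est = float(res.params[test_coef])
        se = float(res.bse[test_coef])
    if not np.isfinite(est) or not np.isfinite(se) or se < SE_DEGENERATE:
        return DGEResult(gene=name, contrast=label, stat=0.0, p=1.0, lfc=est / LN2,
                         flags=["degenerate-fit"])
    z = est / se
    p = float(min(2.0 * st.norm.sf(abs(z)), 1.0))
    return DGEResult(gene=name, contrast=label, stat=float(z), p=p, lfc=est / LN2)


def nb_glm_table(counts, design, offset_log_sf, genes=None, test_coef: int = 1,
                 contrast=None) -> pd.DataFrame:
    """Run :func:`nb_glm_wald` per gene column and BH-adjust over clean fits."""
    X = counts.tocsc() if sp.issparse(counts) else np.asarray(counts)
    n_genes = X.shape[1]
    genes = np.asarray(genes) if genes is not None else np.arange(n_genes)
    rows = []
    for j in range(n_genes):
        col = np.asarray(X[:, j].todense()).ravel() if sp.issparse(X) else X[:, j]
        r = nb_glm_wald(col, design, offset_log_sf, test_coef=test_coef,
                        gene=genes[j], contrast=contrast)
        rows.append({"gene": r.gene, "stat": r.stat, "p": r.p, "lfc": r.lfc,
                     "flags": ";".join(r.flags)})
    tab = pd.DataFrame(rows)
    clean = tab["flags"] == ""
    tab["fdr"] = np.nan
    if clean.any():
        tab.loc[clean, "fdr"] = bh_fdr(tab.loc[clean, "p"].to_numpy())
    return tab


# ---------------------------------------------------------------------------
# selection rules

def _group_lfc(mean_a: float, mean_b: float, eps: float = 1e-9) -> float:
    """log2 fold change between mean log1p-normalized expressions (expm1 scale)."""
    return float(np.log2((np.expm1(mean_a) + eps) / (np.expm1(mean_b) + eps)))


def signed_min_lfc(lfcs) -> float:
    """Reporting convention across comparisons: 0 when signs disagree, else the
    logFC with the smallest absolute value (keeping its sign)."""
    lfcs = np.asarray(lfcs, dtype=float)
    if lfcs.size == 0:
        return 0.0
    if (lfcs > 0).any() and (lfcs < 0).any():
        return 0.0
    return float(lfcs[np.abs(lfcs).argmin()])


def conserved_state_markers(norm_expr, gene_names, state_labels, dataset_labels,
                            sample_labels=None, fdr_max: float = 0.1, min_lfc: float = 0.0,
                            rel_expr=None, rel_expr_min: float = 0.7,
                            representation_frac: float = 0.10) -> pd.DataFrame:
    """Cross-dataset conserved state markers via Welch tests on cell level.

    Groups are state x dataset combinations; a dataset counts for a state when
    at least ``representation_frac`` of any of its samples' cells fall in that
    state. Each group is tested against every other group except groups of the
    same state; a gene is a marker of a state iff significantly up
    (FDR < ``fdr_max``, logFC > ``min_lfc``) in ALL of the state's datasets
    against ALL compared groups. Markers are ranked by highest minimal logFC and
    genes with relative expression in the cell type below ``rel_expr_min`` are
    removed when ``rel_expr`` (per-gene array) is provided.
    """
    X = norm_expr.tocsr() if sp.issparse(norm_expr) else np.asarray(norm_expr)
    gene_names = np.asarray(gene_names)
    states = np.asarray(state_labels)
    datasets = np.asarray(dataset_labels)
    samples = np.asarray(sample_labels) if sample_labels is not None else datasets

    # representation rule
    group_masks: dict[tuple, np.ndarray] = {}
    for s in pd.unique(states):
        for d in pd.unique(datasets):
            in_sd = (states == s) & (datasets == d)
            if not in_sd.any():
                continue
            ok = False
            for smp in pd.unique(samples[datasets == d]):
                cells = (samples == smp)
                if cells.sum() and (in_sd & cells).sum() / cells.sum() >= representation_frac:
                    ok = True
                    break
            if ok:
                group_masks[(s, d)] = in_sd
    states_present = sorted({s for s, _ in group_masks})
    if not states_present:
        raise ValueError("no state x dataset group passes the representation rule")

    dense = {g: np.asarray(X[m].todense()) if sp.issparse(X) else X[m]
             for g, m in group_masks.items()}
    n_genes = gene_names.size

    records = []
    for s in states_present:
        own = [g for g in group_masks if g[0] == s]
        others = [g for g in group_masks if g[0] != s]
        if not others:
            continue
        ok_all = np.ones(n_genes, dtype=bool)
        min_lfc_seen = np.full(n_genes, np.inf)
        lfc_signs_pos = np.ones(n_genes, dtype=bool)
        lfc_signs_neg = np.ones(n_genes, dtype=bool)
        max_fdr_seen = np.zeros(n_genes)
        all_lfcs = np.full((len(own) * len(others), n_genes), np.nan)
        ci = 0
        for ga in own:
            A = dense[ga]
            for gb in others:
                B = dense[gb]
                t, p = st.ttest_ind(A, B, equal_var=False, axis=0)
                p = np.where(np.isfinite(p), p, 1.0)
                q = bh_fdr(p)
                ma, mb = A.mean(axis=0), B.mean(axis=0)
                lfc = np.log2((np.expm1(ma) + 1e-9) / (np.expm1(mb) + 1e-9))
                ok_all &= (q < fdr_max) & (lfc > min_lfc) & (t > 0)
                min_lfc_seen = np.minimum(min_lfc_seen, lfc)
                max_fdr_seen = np.maximum(max_fdr_seen, q)
                all_lfcs[ci] = lfc
                ci += 1
        for j in np.where(ok_all)[0]:
            records.append({
                "gene": gene_names[j], "state": s,
                "max_fdr": float(max_fdr_seen[j]),
                "signed_min_lfc": signed_min_lfc(all_lfcs[:, j]),
                "min_lfc": float(min_lfc_seen[j]),
            })
    out = pd.DataFrame(records, columns=["gene", "state", "max_fdr", "signed_min_lfc", "min_lfc"])
    if rel_expr is not None and len(out):
        rel = pd.Series(np.asarray(rel_expr, dtype=float), index=gene_names)
        out = out[out["gene"].map(rel) >= rel_expr_min]
    return out.sort_values(["state", "min_lfc"], ascending=[True, False]).reset_index(drop=True)


def trajectory_dge(counts, gene_names, process, size_factors, condition,
                   dataset_labels=None, rel_expr=None, min_expr_frac: float = 0.05,
                   fdr: float = 0.05, min_abs_lfc: float = 1.0,
                   rel_expr_min: float = 0.2) -> pd.DataFrame:
    """Linear change along the continuous disease process, NB-GLM Wald per gene.

    Genes expressed in fewer than ``min_expr_frac`` of both the healthy and the
    diseased cells are not tested. Dataset is added as a covariate when
    ``dataset_labels`` has more than one level. DEG flag = FDR < ``fdr``,
    |lfc| > ``min_abs_lfc`` and relative expression above ``rel_expr_min``
    (when provided).
    """
    X = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(counts)
    gene_names = np.asarray(gene_names)
    condition = np.asarray(condition)
    process = np.asarray(process, dtype=float)

    healthy = condition == "healthy"
    diseased = ~healthy
    frac_h = np.asarray((X[np.where(healthy)[0]] > 0).mean(axis=0)).ravel()
    frac_d = np.asarray((X[np.where(diseased)[0]] > 0).mean(axis=0)).ravel()
    tested = (frac_h >= min_expr_frac) | (frac_d >= min_expr_frac)

    cols = [np.ones(X.shape[0]), process]
    if dataset_labels is not None:
        ds = pd.get_dummies(pd.Series(np.asarray(dataset_labels)), drop_first=True)
        if ds.shape[1]:
            cols.extend(ds.to_numpy(dtype=float).T)
    design = np.column_stack(cols)
    offset = np.log(np.asarray(size_factors, dtype=float))

    tab = nb_glm_table(X[:, np.where(tested)[0]], design, offset,
                       genes=gene_names[tested], test_coef=1)
    tab["tested"] = True
    tab["rel_expr"] = (pd.Series(np.asarray(rel_expr, dtype=float), index=gene_names)
                       .reindex(tab["gene"]).to_numpy() if rel_expr is not None else np.nan)
    sig = (tab["fdr"] < fdr) & (tab["lfc"].abs() > min_abs_lfc) & (tab["flags"] == "")
    if rel_expr is not None:
        sig &= tab["rel_expr"] > rel_expr_min
    tab["is_deg"] = sig.fillna(False)

    untested = pd.DataFrame({"gene": gene_names[~tested]})
    untested["stat"] = np.nan
    untested["p"] = np.nan
    untested["lfc"] = np.nan
    untested["flags"] = "low-expression"
    untested["fdr"] = np.nan
    untested["tested"] = False
    untested["rel_expr"] = np.nan
    untested["is_deg"] = False
    return pd.concat([tab, untested], ignore_index=True)


def pairwise_celltype_markers(pb, celltype_key: str = "cell_type",
                              covariate_keys=("sex",), fdr: float = 0.05,
                              min_lfc: float = 1.5, gene_names=None,
                              min_total: int = 10) -> pd.DataFrame:
    """One-vs-rest cell-type markers from a joint NB-GLM on metadata pseudobulks.

    One model per gene with cell-type factors plus covariates and log total
    counts as offset; for each type every pairwise contrast against the other
    types is Wald-tested, and a marker must pass FDR < ``fdr`` and
    log2 FC > ``min_lfc`` against ALL other types. Reported per the marker
    convention (max adjusted p across comparisons; signed minimal logFC, 0 on
    sign conflict).
    """
    keys = pb.keys
    Y = np.asarray(pb.profiles, dtype=float)
    gene_names = np.asarray(gene_names) if gene_names is not None else np.arange(Y.shape[1])

    cts = pd.unique(keys[celltype_key])
    ct_counts = keys[celltype_key].value_counts()
    cts = [c for c in cts if ct_counts[c] >= 2]
    if len(cts) < 2:
        raise ValueError("need at least two cell types with >= 2 pseudobulks")
    use = keys[celltype_key].isin(cts).to_numpy()
    keys = keys[use].reset_index(drop=True)
    Y = Y[use]

    ct_d = pd.get_dummies(keys[celltype_key], drop_first=False).astype(float)
    ct_names = list(ct_d.columns)
    cols = [np.ones(len(keys))] + [ct_d[c].to_numpy() for c in ct_names[1:]]
    for ck in covariate_keys:
        if ck in keys:
            cv = pd.get_dummies(keys[ck], drop_first=True).astype(float)
            cols.extend(cv.to_numpy().T)
    design = np.column_stack(cols)
    totals = Y.sum(axis=1)
    if (totals < min_total).any():
        keep = totals >= min_total
        design, Y, totals = design[keep], Y[keep], totals[keep]
        keys = keys[keep].reset_index(drop=True)
    offset = np.log(np.maximum(totals, 1.0))

    # coefficient of cell type c relative to the dropped baseline ct_names[0]
    def ct_vector(c):
        v = np.zeros(design.shape[1])
        if c != ct_names[0]:
            v[1 + ct_names[1:].index(c)] = 1.0
        return v

    pairs = [(a, b) for a in ct_names for b in ct_names if a != b]
    pair_stats = {}
    for a, b in pairs:
        if (b, a) in pair_stats:  # reuse symmetric fit results
            t = pair_stats[(b, a)]
            pair_stats[(a, b)] = t.assign(lfc=-t["lfc"], stat=-t["stat"])
            continue
        c = ct_vector(a) - ct_vector(b)
        tab = nb_glm_table(np.round(Y).astype(int), design, offset,
                           genes=gene_names, contrast=c)
        pair_stats[(a, b)] = tab

    records = []
    for a in ct_names:
        comp = [pair_stats[(a, b)] for b in ct_names if b != a]
        ok = np.ones(len(gene_names), dtype=bool)
        maxq = np.zeros(len(gene_names))
        lfcs = np.zeros((len(comp), len(gene_names)))
        for i, tab in enumerate(comp):
            q = tab["fdr"].to_numpy()
            q = np.where(np.isfinite(q), q, 1.0)
            lfc = tab["lfc"].to_numpy()
            ok &= (q < fdr) & (lfc > min_lfc) & (tab["flags"] == "").to_numpy()
            maxq = np.maximum(maxq, q)
            lfcs[i] = lfc
        for j in np.where(ok)[0]:
            records.append({"gene": gene_names[j], "cell_type": a,
                            "max_fdr": float(maxq[j]),
                            "signed_min_lfc": signed_min_lfc(lfcs[:, j])})
    return pd.DataFrame(records, columns=["gene", "cell_type", "max_fdr", "signed_min_lfc"])


def cluster_deg_groups(deg_table: pd.DataFrame, pseudobulk_profiles, gene_names,
                       norm_expr=None, cut: float | None = None, min_size: int = 2,
                       n_trim: int = 20, seed: int = 0) -> dict:
    """Split DEGs by logFC sign and hierarchically cluster each direction on
    fine-pseudobulk profiles; optionally score each group per cell
    (control-matched gene-set score, winsorized to [0,1])."""
    from .programs import _gene_correlation_distance, minmax_winsorized, score_gene_set
    from scipy.cluster.hierarchy import average, fcluster
    from scipy.spatial.distance import squareform

    gene_names = np.asarray(gene_names)
    gidx = {g: i for i, g in enumerate(gene_names)}
    out = {}
    degs = deg_table[deg_table["is_deg"]]
    for direction, sub in (("up", degs[degs["lfc"] > 0]), ("down", degs[degs["lfc"] < 0])):
        genes = [g for g in sub["gene"] if g in gidx]
        if len(genes) == 0:
            out[direction] = []
            continue
        if len(genes) < 2:
            groups = [genes]
        else:
            prof = np.asarray(pseudobulk_profiles)[:, [gidx[g] for g in genes]].T
            D = _gene_correlation_distance(prof)
            np.fill_diagonal(D, 0.0)
            Z = average(squareform(D, checks=False))
            cut_h = 0.5 * Z[:, 2].max() if cut is None else cut
            labels = fcluster(Z, t=max(cut_h, 1e-12), criterion="distance")
            groups = [[g for g, l in zip(genes, labels) if l == gid]
                      for gid in np.unique(labels)]
            groups = [g for g in groups if len(g) >= min_size]
            groups.sort(key=lambda m: (-len(m), m[0]))
        entries = []
        for i, g in enumerate(groups):
            entry = {"id": f"{direction}{i}", "genes": g}
            if norm_expr is not None:
                raw = score_gene_set(norm_expr, gene_names, g, seed=seed + i)
                entry["score"] = minmax_winsorized(raw, n_trim=n_trim)
            entries.append(entry)
        out[direction] = entries
    return out


def conserved_condition_genes(per_dataset_dge: dict, fdr: float = 0.25, min_lfc: float = 0.5,
                              min_frac_datasets: float = 0.5) -> list:
    """Genes passing FDR and logFC thresholds in at least ``min_frac_datasets``
    of the datasets where they were tested-eligible.

    Each value of ``per_dataset_dge`` is a DGE table with columns
    gene / fdr / lfc / tested; tested=False marks genes failing that dataset's
    expression rule, so they cannot count as passing there. The required number
    of passes is ``ceil(min_frac_datasets * n_datasets)``.
    """
    n_datasets = len(per_dataset_dge)
    if n_datasets == 0:
        return []
    need = int(np.ceil(min_frac_datasets * n_datasets))
    passes: dict = {}
    for tab in per_dataset_dge.values():
        t = tab[tab.get("tested", pd.Series(True, index=tab.index)).fillna(False)]
        sel = t[(t["fdr"] < fdr) & (t["lfc"] > min_lfc)]
        for g in sel["gene"]:
            passes[g] = passes.get(g, 0) + 1
    return sorted(g for g, k in passes.items() if k >= need)


def marker_translation_test(per_dataset_expr: dict, per_dataset_mask: dict,
                            markers, gene_names, alpha: float = 0.05) -> pd.DataFrame:
    """Does each marker translate to the external datasets?

    Per dataset, one-sided Welch t (target group greater); verdict "translates"
    iff significant in every dataset where the group exists. log2 FC of group
    means is reported per dataset.
    """
    gene_names = np.asarray(gene_names)
    gidx = {g: i for i, g in enumerate(gene_names)}
    rows = []
    for g in markers:
        if g not in gidx:
            continue
        j = gidx[g]
        verdict = True
        n_used = 0
        lfcs = {}
        for d, X in per_dataset_expr.items():
            mask = np.asarray(per_dataset_mask[d], dtype=bool)
            if mask.sum() < 2 or (~mask).sum() < 2:
                continue
            col = np.asarray(X[:, j].todense()).ravel() if sp.issparse(X) else np.asarray(X)[:, j]
            t, df, p = welch_t(col[mask], col[~mask])
            p_one = p / 2 if t > 0 else 1 - p / 2
            verdict &= p_one < alpha
            n_used += 1
            lfcs[d] = _group_lfc(col[mask].mean(), col[~mask].mean())
        rows.append({"gene": g, "translates": bool(verdict and n_used > 0),
                     "n_datasets": n_used,
                     **{f"lfc_{d}": v for d, v in lfcs.items()}})
    return pd.DataFrame(rows)
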
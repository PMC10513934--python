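"""Gene programs: sparsity-bias-corrected Moran's I gene selection, program
clustering, control-matched gene-set scoring, winsorized normalization,
conserved healthy-heterogeneity gene groups, and PC-regression variance
explained with an empirical null.

Moran's I over a cell-embedding graph is biased downward for genes detected in
few cells: sampling zeros destroy local smoothness even when the underlying
signal is shared. The correction regresses a "baseline" trend of I on
log10(number of expressing cells) using genes unlikely to be truly variable
(the lowest-I genes within equal-frequency sparsity bins, after excluding the
most ubiquitously expressed genes) and reports residuals from this trend, so
lowly and highly expressed genes compete on equal footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from ._utils import as_dense, equal_frequency_bins


@dataclass
class CorrectedMoran:
    table: pd.DataFrame  # columns: gene, I, n_expressed, corrected_I, used_in_baseline
    slope: float
    intercept: float

    def top_genes(self, top_k: int | None = None, threshold: float | None = None) -> list:
        t = self.table.sort_values(["corrected_I", "gene"], ascending=[False, True])
        if threshold is not None:
            t = t[t["corrected_I"] > threshold]
        if top_k is not None:
            t = t.head(top_k)
        return t["gene"].tolist()


@dataclass
class GeneProgram:
    id: str
    genes: list
    score: np.ndarray | None = None
    enrichment: dict = field(default_factory=dict)


def corrected_morans_i(I_per_gene, n_expressed, genes=None, high_expr_cutoff: float | None = None,
                       n_bins: int = 20, per_bin: int = 5, log_transform: bool = True) -> CorrectedMoran:
    """Residual Moran's I after regressing out the expression-sparsity baseline.

    ``high_expr_cutoff`` (absolute cell count) excludes ubiquitously expressed
    genes from the baseline fit only; their corrected score is still computed.
    Baseline genes: ``per_bin`` lowest-I genes per equal-frequency n_expressed
    bin; OLS of I on log10(n_expressed) (or raw n_expressed when
    ``log_transform=False``).
    """
    I = np.asarray(I_per_gene, dtype=float)
    n_expr = np.asarray(n_expressed, dtype=float)
    if genes is None:
        genes = np.arange(I.size)
    genes = np.asarray(genes)
    ok = np.isfinite(I) & (n_expr > 0)
    if not ok.all():
        I, n_expr, genes = I[ok], n_expr[ok], genes[ok]

    eligible = np.ones(I.size, dtype=bool)
    if high_expr_cutoff is not None:
        eligible = n_expr < high_expr_cutoff
    n_eligible = int(eligible.sum())
    if n_eligible < n_bins * per_bin:
        per_bin = max(1, n_eligible // max(n_bins, 1))
        warnings.warn(f"few eligible baseline genes; reducing per_bin to {per_bin}")
    if n_eligible < 2:
        raise ValueError("not enough genes below high_expr_cutoff to fit the baseline")

    idx_elig = np.where(eligible)[0]
    bins = equal_frequency_bins(n_expr[idx_elig], n_bins)
    baseline_idx = []
    for b in np.unique(bins):
        members = idx_elig[bins == b]
        order = members[np.lexsort((members, I[members]))]
        baseline_idx.extend(order[:per_bin].tolist())
    baseline_idx = np.asarray(baseline_idx)

    x = np.log10(n_expr) if log_transform else n_expr
    xb, yb = x[baseline_idx], I[baseline_idx]
    slope, intercept = np.polyfit(xb, yb, 1) if len(baseline_idx) > 1 else (0.0, float(yb.mean()))
    corrected = I - (intercept + slope * x)

    used = np.zeros(I.size, dtype=bool)
    used[baseline_idx] = True
    table = pd.DataFrame({
        "gene": genes, "I": I, "n_expressed": n_expr.astype(int),
        "corrected_I": corrected, "used_in_baseline": used,
    })
    return CorrectedMoran(table=table, slope=float(slope), intercept=float(intercept))


def _gene_correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson r between gene rows, NaN-safe, clipped to [0, 2]."""
    P = as_dense(profiles)
    sd = P.std(axis=1)
    Z = (P - P.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    corr = Z @ Z.T / P.shape[1]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(1.0 - corr, 0.0, 2.0)


def cluster_gene_programs(selected_genes, pseudobulk_profiles, cut: float | None = None,
                          min_size: int = 5) -> list[GeneProgram]:
    """Group coexpressed genes into disjoint programs.

    ``pseudobulk_profiles``: genes x pseudobulks matrix (rows aligned with
    ``selected_genes``). Average-linkage hierarchical clustering on Pearson
    correlation distance; the cut (default 0.5 x maximum merge height) yields
    disjoint programs, and programs smaller than ``min_size`` are dropped.
    """
    selected_genes = list(selected_genes)
    if len(selected_genes) < 2:
        raise ValueError("need at least 2 selected genes")
    D = _gene_correlation_distance(pseudobulk_profiles)
    np.fill_diagonal(D, 0.0)
    if D.max() <= 1e-12:  # all genes identical
        return [GeneProgram(id="program0", genes=selected_genes)]
    Z = average(squareform(D, checks=False))
    cut_h = 0.5 * Z[:, 2].max() if cut is None else cut
    labels = fcluster(Z, t=cut_h, criterion="distance")
    programs = []
    for pid in np.unique(labels):
        members = [g for g, l in zip(selected_genes, labels) if l == pid]
        if len(members) >= min_size:
            programs.append(members)
    programs.sort(key=lambda m: (-len(m), m[0] if m else ""))
    return [GeneProgram(id=f"program{i}", genes=m) for i, m in enumerate(programs)]


def score_gene_set(norm_expr, gene_names, gene_set, n_ctrl_bins: int = 25,
                   ctrl_size: int = 50, seed: int = 0) -> np.ndarray:
    """Per-cell activity score of a gene set against expression-matched controls.

    score = mean expression over the set minus mean over control genes drawn
    (seeded) from the same mean-expression bins as the set members, excluding
    the set itself. Missing set genes are dropped.
    """
    gene_names = np.asarray(gene_names)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    set_idx = np.asarray([name_to_idx[g] for g in gene_set if g in name_to_idx])
    if set_idx.size == 0:
        raise ValueError("gene set has empty intersection with measured genes")

    mean_expr = np.asarray(norm_expr.mean(axis=0)).ravel()
    bins = equal_frequency_bins(mean_expr, n_ctrl_bins)
    rng = np.random.default_rng(int(seed) % (2**31))
    in_set = np.zeros(gene_names.size, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[int] = []
    for b in np.unique(bins[set_idx]):
        candidates = np.where((bins == b) & ~in_set)[0]
        if candidates.size == 0:
            continue
        take = min(ctrl_size, candidates.size)
        ctrl_idx.extend(rng.choice(candidates, size=take, replace=False).tolist())
    if not ctrl_idx:
        # every bin shared with the set is exhausted (tiny gene universes):
        # fall back to sampling controls from all non-set genes
        pool = np.where(~in_set)[0]
        if pool.size == 0:
            raise ValueError("no control genes available outside the gene set")
        warnings.warn("control bins exhausted; sampling controls from all non-set genes")
        ctrl_idx = rng.choice(pool, size=min(ctrl_size, pool.size), replace=False).tolist()

    set_mean = np.asarray(norm_expr[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(norm_expr[:, np.asarray(ctrl_idx)].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def minmax_winsorized(scores, n_trim: int = 20) -> np.ndarray:
    """[0,1] min-max normalization with the scaling range set after removing the
    ``n_trim`` highest and lowest cells; out-of-range values are clipped."""
    s = np.asarray(scores, dtype=float)
    n = s.size
    if np.ptp(s) == 0:
        return np.full(n, 0.5)
    if n > 2 * n_trim:
        srt = np.sort(s)
        lo, hi = srt[n_trim], srt[n - 1 - n_trim]
    else:
        warnings.warn("too few cells to winsorize; falling back to plain min-max")
        lo, hi = s.min(), s.max()
    if hi <= lo:
        return np.full(n, 0.5)
    return np.clip((s - lo) / (hi - lo), 0.0, 1.0)


def conserved_variable_gene_groups(per_sample_expr: dict, per_sample_graphs: dict,
                                   per_sample_pseudobulk: dict, gene_names,
                                   min_expr_frac: float = 0.30, top_k: int = 300,
                                   cut: float | None = None, min_size: int = 5,
                                   n_bins: int = 20, per_bin: int = 5) -> list[GeneProgram]:
    """Gene groups variable across cells in every healthy sample.

    Per sample, bias-corrected Moran's I is computed (baseline excludes genes
    expressed in >= ``min_expr_frac`` of that sample's cells) and the top
    ``top_k`` genes retained; only genes passing in ALL samples survive. The
    gene-gene distance is the maximum over samples of the per-sample Pearson
    correlation distance on fine pseudobulks, clustered with average linkage.
    """
    from .graph import morans_i_genes

    if len(per_sample_expr) < 2:
        raise ValueError("need at least 2 samples")
    gene_names = np.asarray(gene_names)
    selected_sets = []
    for s, X in per_sample_expr.items():
        I = morans_i_genes(X, per_sample_graphs[s])
        n_expr = np.asarray((X > 0).sum(axis=0)).ravel()
        cutoff = min_expr_frac * X.shape[0]
        cm = corrected_morans_i(I, n_expr, genes=gene_names, high_expr_cutoff=cutoff,
                                n_bins=n_bins, per_bin=per_bin)
        selected_sets.append(set(cm.top_genes(top_k=top_k)))
    conserved = sorted(set.intersection(*selected_sets))
    if not conserved:
        warnings.warn("no gene passes the corrected-I selection in all samples")
        return []
    if len(conserved) == 1:
        return [GeneProgram(id="group0", genes=conserved)]

    gidx = {g: i for i, g in enumerate(gene_names)}
    rows = [gidx[g] for g in conserved]
    D = np.zeros((len(conserved), len(conserved)))
    for s, pb in per_sample_pseudobulk.items():
        prof = as_dense(pb.profiles)[:, rows].T  # genes x pseudobulks
        D = np.maximum(D, _gene_correlation_distance(prof))
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    cut_h = 0.5 * Z[:, 2].max() if cut is None else cut
    labels = fcluster(Z, t=cut_h, criterion="distance")
    groups = []
    for gid in np.unique(labels):
        members = [g for g, l in zip(conserved, labels) if l == gid]
        if len(members) >= min_size:
            groups.append(members)
    groups.sort(key=lambda m: (-len(m), m[0]))
    return [GeneProgram(id=f"group{i}", genes=m) for i, m in enumerate(groups)]


def explained_variance(norm_expr, gene_names, programs: list[GeneProgram],
                       hvgs=None, n_pcs: int = 50, n_rand: int = 100,
                       seed: int = 0) -> dict:
    """Share of principal-component variance explained by gene-program scores.

    PCs are computed on (centered) HVG expression; each PC's scores are
    regressed on the GP score matrix and the total explained variance is
    sum_k R^2_k * varratio_k. A null distribution from size-matched random gene
    groups (scored identically) yields a one-sided empirical p-value
    (1 + #{null >= observed}) / (1 + n_rand).
    """
    from sklearn.decomposition import PCA

    gene_names = np.asarray(gene_names)
    X = as_dense(norm_expr if hvgs is None else norm_expr[:, [
        int(np.where(gene_names == h)[0][0]) for h in hvgs]])
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, random_state=int(seed) % (2**31))
    pcs = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    varratio = pca.explained_variance_ratio_

    def total_ev(score_mat: np.ndarray) -> tuple[float, np.ndarray]:
        S = np.column_stack([np.ones(score_mat.shape[0]), score_mat])
        # drop collinear columns via rank-revealing QR on the design
        q, r = np.linalg.qr(S)
        keep = np.abs(np.diag(r)) > 1e-10 * max(abs(np.diag(r)).max(), 1e-300)
        S = S[:, keep]
        coef, *_ = np.linalg.lstsq(S, pcs, rcond=None)
        fitted = S @ coef
        ss_res = ((pcs - fitted) ** 2).sum(axis=0)
        ss_tot = ((pcs - pcs.mean(axis=0)) ** 2).sum(axis=0)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), 0.0)
        return float((r2 * varratio).sum()), r2

    scores = np.column_stack([
        p.score if p.score is not None else
        score_gene_set(norm_expr, gene_names, p.genes, seed=seed)
        for p in programs
    ])
    observed, r2 = total_ev(scores)

    per_gp = {}
    for j, p in enumerate(programs):
        ev_j, _ = total_ev(scores[:, [j]])
        per_gp[p.id] = ev_j

    rng = np.random.default_rng(int(seed) % (2**31) + 1)
    sizes = [len(p.genes) for p in programs]
    null = np.empty(n_rand)
    for r in range(n_rand):
        rand_scores = np.column_stack([
            score_gene_set(norm_expr, gene_names,
                           rng.choice(gene_names, size=sz, replace=False),
                           seed=int(rng.integers(2**31)))
            for sz in sizes
        ])
        null[r], _ = total_ev(rand_scores)
    p_emp = (1.0 + (null >= observed).sum()) / (1.0 + n_rand)
    return {"total_ev": observed, "per_gp_ev": per_gp, "null": null,
            "empirical_p": float(p_emp), "varratio": varratio, "pc_r2": r2}
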
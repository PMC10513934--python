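"""Ambient RNA gene detection from near-empty droplets and the relative-expression metric.

Ambient transcripts contaminate every droplet in a sample; their gene profile
is estimated from droplets with fewer than ~100 total counts, which contain
essentially no cell. Genes dominating this profile (in islets, hormone genes
such as Ins1/2, Gcg, Sst) are flagged per sample and pooled across samples.
The per-gene relative-expression metric (cluster means maxabs-scaled across
fine clusters) then separates ambient genes genuinely expressed in a target
cell type from those whose signal there is purely ambient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from ._utils import as_dense


@dataclass
class AmbientProfile:
    sample: str
    gene_proportion: np.ndarray
    n_droplets_used: int
    max_count_threshold: int = 100

    def __post_init__(self):
        p = np.asarray(self.gene_proportion, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("gene proportions must be nonnegative and sum to 1")
        self.gene_proportion = p


def ambient_profile(raw_counts, sample: str = "", max_count: int = 100) -> AmbientProfile:
    """Per-gene ambient proportions from sub-threshold droplets of one sample.

    ``raw_counts`` is droplets x genes including the near-empty droplets;
    droplets with total counts >= ``max_count`` contribute nothing.
    """
    X = raw_counts.tocsr() if sp.issparse(raw_counts) else sp.csr_matrix(raw_counts)
    totals = np.asarray(X.sum(axis=1)).ravel()
    sub = totals < max_count
    if not sub.any():
        raise ValueError(f"sample {sample!r}: no droplets with < {max_count} counts")
    gene_sums = np.asarray(X[sub].sum(axis=0)).ravel().astype(float)
    total = gene_sums.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r}: sub-threshold droplets contain no counts")
    return AmbientProfile(sample=sample, gene_proportion=gene_sums / total,
                          n_droplets_used=int(sub.sum()), max_count_threshold=max_count)


def top_ambient_genes(profiles: list[AmbientProfile], small_target: int = 20,
                      large_target: int = 100) -> tuple[list[int], list[int]]:
    """Two nested ambient gene sets (indices), pooled as unions across samples.

    Per sample a proportion threshold is placed at the ``target``-th ranked gene
    so the per-sample set has approximately the target size (ties included);
    the small set uses ``small_target``, the permissive set ``large_target``.
    """
    if not profiles:
        raise ValueError("need at least one ambient profile")
    n_genes = profiles[0].gene_proportion.size
    if small_target > n_genes or large_target > n_genes:
        raise ValueError("target set size exceeds number of genes")
    if small_target > large_target:
        raise ValueError("small_target must be <= large_target")

    def union(target: int) -> set[int]:
        pooled: set[int] = set()
        for prof in profiles:
            p = prof.gene_proportion
            # threshold at the target-th ranked proportion (ties broken by index)
            order = np.lexsort((np.arange(n_genes), -p))
            sel = order[:target][p[order[:target]] > 0]
            pooled.update(int(i) for i in sel)
        return pooled

    small = union(small_target)
    large = union(large_target) | small  # nesting guaranteed even with ties
    return sorted(small), sorted(large)


def relative_expression(norm_expr, cluster_labels, cluster_to_celltype: dict | None = None,
                        cell_types=None) -> pd.DataFrame:
    """Per-gene relative expression in each cell type, in [0, 1].

    Cluster mean expression is maxabs-scaled across clusters per gene; a gene's
    relative expression in cell type T is the maximum scaled value over clusters
    assigned to T. If ``cluster_to_celltype`` is not given it is derived from
    per-cell ``cell_types``: a cluster is assigned to its modal cell type when
    that label exceeds 50% of member cells (otherwise the cluster is unassigned).
    """
    labels = np.asarray(cluster_labels)
    clusters = pd.unique(labels)
    means = np.vstack([
        np.asarray(norm_expr[labels == c].mean(axis=0)).ravel() for c in clusters
    ])  # clusters x genes
    maxabs = np.abs(means).max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(maxabs > 0, means / np.maximum(maxabs, 1e-300), 0.0)

    if cluster_to_celltype is None:
        if cell_types is None:
            raise ValueError("provide cluster_to_celltype or per-cell cell_types")
        cell_types = np.asarray(cell_types)
        cluster_to_celltype = {}
        for c in clusters:
            m = labels == c
            vals, counts = np.unique(cell_types[m], return_counts=True)
            j = counts.argmax()
            if counts[j] > 0.5 * m.sum():
                cluster_to_celltype[c] = vals[j]

    types = sorted({t for t in cluster_to_celltype.values()})
    out = np.zeros((rel.shape[1], len(types)))
    for jt, t in enumerate(types):
        rows = [i for i, c in enumerate(clusters) if cluster_to_celltype.get(c) == t]
        if rows:
            out[:, jt] = rel[rows].max(axis=0)
    return pd.DataFrame(np.clip(out, 0.0, 1.0), columns=types)


def cluster_relative_profiles(norm_expr, cluster_labels) -> np.ndarray:
    """Maxabs-scaled per-cluster mean profiles (genes x clusters), for grouping genes."""
    labels = np.asarray(cluster_labels)
    clusters = pd.unique(labels)
    means = np.vstack([
        np.asarray(norm_expr[labels == c].mean(axis=0)).ravel() for c in clusters
    ]).T  # genes x clusters
    maxabs = np.abs(means).max(axis=1, keepdims=True)
    return np.where(maxabs > 0, means / np.maximum(maxabs, 1e-300), 0.0)


def non_celltype_ambient_genes(ambient_genes: list[int], relative_profiles: np.ndarray,
                               rel_expr_in_type: np.ndarray, cutoff: float = 0.5,
                               n_groups: int | None = None) -> list[int]:
    """Ambient genes whose gene group shows low relative expression in the target type.

    ``relative_profiles`` are per-cluster relative profiles for the ambient genes
    (rows aligned with ``ambient_genes``); genes are grouped by hierarchical
    clustering (Pearson-correlation distance, average linkage, cut to
    ``max(2, ceil(n/5))`` groups unless overridden) and a group is flagged when
    its maximum ``rel_expr_in_type`` is below ``cutoff``.
    """
    genes = list(ambient_genes)
    if not genes:
        return []
    rel_t = np.asarray(rel_expr_in_type, dtype=float)
    if len(genes) == 1:
        return genes if rel_t[0] < cutoff else []

    P = as_dense(relative_profiles)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(P)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    k = n_groups if n_groups is not None else max(2, int(np.ceil(len(genes) / 5)))
    groups = fcluster(Z, t=min(k, len(genes)), criterion="maxclust")

    flagged = []
    for gid in np.unique(groups):
        m = groups == gid
        if rel_t[m].max() < cutoff:
            flagged.extend(np.asarray(genes)[m].tolist())
    return sorted(flagged, key=genes.index)
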
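"""Cell QC filtering, per-sample normalization + log1p, and batch-aware HVG selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from ._utils import equal_frequency_bins


@dataclass
class QCThresholds:
    min_genes: int = 200
    min_counts: int = 500
    max_counts: float = np.inf
    max_mito_frac: float = 0.2
    mito_gene_prefix: str = "mt-"

    def __post_init__(self):
        if self.min_counts > self.max_counts:
            raise ValueError("min_counts must be <= max_counts")
        if not (0 <= self.max_mito_frac <= 1):
            raise ValueError("max_mito_frac must be in [0, 1]")


def filter_cells(adata: AnnData, thresholds: QCThresholds) -> tuple[AnnData, pd.DataFrame]:
    """Remove cells failing any QC rule; returns filtered data plus a per-rule report.

    Rules: number of expressed genes, total counts (low and high) and
    mitochondrial fraction (genes matched by name prefix, case-insensitive).
    """
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    n_genes = X.getnnz(axis=1)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = np.array([g.lower().startswith(thresholds.mito_gene_prefix.lower())
                          for g in adata.var_names])
    mito = (np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any()
            else np.zeros(adata.n_obs))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)

    fails = {
        "low_n_genes": n_genes < thresholds.min_genes,
        "low_counts": totals < thresholds.min_counts,
        "high_counts": totals > thresholds.max_counts,
        "high_mito": mito_frac > thresholds.max_mito_frac,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    if not keep.any():
        raise ValueError(
            "QC removed all cells; thresholds "
            f"{thresholds} vs median counts {np.median(totals):.0f}, "
            f"median genes {np.median(n_genes):.0f}"
        )
    report = pd.DataFrame({
        "rule": list(fails) + ["total_removed", "retained"],
        "n_cells": [int(v.sum()) for v in fails.values()] + [int((~keep).sum()), int(keep.sum())],
    })
    return adata[keep].copy(), report


def normalize_log1p(adata: AnnData, method: str = "total", sample_key: str = "sample") -> AnnData:
    """Per-sample depth normalization followed by log(x+1).

    ``total``: size factor = cell total / median total within the sample, so
    after division every cell's total equals the sample median total.
    ``median_ratio``: per-sample median of ratios to the sample mean profile
    (computed over genes detected in the cell), rescaled to geometric mean 1
    within the sample.

    Stores size factors in ``obs['size_factor']`` and the normalized matrix in
    ``layers['lognorm']``.
    """
    if method not in ("total", "median_ratio"):
        raise ValueError(f"unknown normalization method {method!r}")
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-count cells present; run filter_cells first")

    samples = adata.obs[sample_key].to_numpy() if sample_key in adata.obs else np.zeros(adata.n_obs)
    sf = np.empty(adata.n_obs)
    for s in pd.unique(samples):
        m = samples == s
        if method == "total":
            sf[m] = totals[m] / np.median(totals[m])
        else:
            Xm = X[m].toarray()
            ref = Xm.mean(axis=0)
            ratios = np.where(ref > 0, Xm / np.maximum(ref, 1e-300), np.nan)
            ratios[Xm == 0] = np.nan
            cell_sf = np.nanmedian(ratios, axis=1)
            cell_sf = np.where(np.isfinite(cell_sf) & (cell_sf > 0), cell_sf, 1.0)
            cell_sf /= np.exp(np.mean(np.log(cell_sf)))
            sf[m] = cell_sf

    norm = X.astype(float).copy()
    norm = sp.diags(1.0 / sf) @ norm
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.obs["size_factor"] = sf
    out.layers["lognorm"] = norm.tocsr()
    return out


def _per_batch_dispersion_rank(Xb: sp.spmatrix, n_bins: int = 20) -> np.ndarray:
    """cell_ranger-flavor ranking: z-scored dispersion within equal-frequency mean bins.

    Returns per-gene rank (0 = most variable); zero-dispersion genes rank last,
    ties broken by gene index.
    """
    Xb = Xb.tocsc()
    n = Xb.shape[0]
    mean = np.asarray(Xb.mean(axis=0)).ravel()
    sq = np.asarray(Xb.multiply(Xb).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    bins = equal_frequency_bins(mean, n_bins)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std()
        z[m] = (disp[m] - mu) / sd if sd > 0 else 0.0
    z[disp == 0] = -np.inf  # constant genes never precede genes with variance
    order = np.lexsort((np.arange(len(z)), -z))
    ranks = np.empty(len(z), dtype=int)
    ranks[order] = np.arange(len(z))
    return ranks


def hvg_batch(adata: AnnData, n_top: int = 2000, batch_key: str = "sample",
              layer: str = "lognorm", n_bins: int = 20) -> list[str]:
    """Batch-aware highly-variable-gene selection.

    Per batch, genes are ranked by binned normalized dispersion; the final list
    orders genes by (number of batches where the gene is in that batch's top
    ``n_top``, descending), then median cross-batch rank, then gene index, and
    returns the first ``min(n_top, n_genes)``.
    """
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize_log1p first")
    X = adata.layers[layer]
    X = X if sp.issparse(X) else sp.csr_matrix(X)
    batches = (adata.obs[batch_key].to_numpy() if batch_key in adata.obs
               else np.zeros(adata.n_obs))
    n_genes = adata.n_vars
    if n_top > n_genes:
        import warnings
        warnings.warn(f"n_top={n_top} > n_genes={n_genes}; returning all genes")
        n_top = n_genes

    ranks = []
    for b in pd.unique(batches):
        m = batches == b
        if m.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 cells")
        ranks.append(_per_batch_dispersion_rank(X[np.where(m)[0]], n_bins=n_bins))
    ranks = np.vstack(ranks)

    n_hits = (ranks < n_top).sum(axis=0)
    med_rank = np.median(ranks, axis=0)
    order = np.lexsort((np.arange(n_genes), med_rank, -n_hits))
    return [adata.var_names[i] for i in order[:n_top]]
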
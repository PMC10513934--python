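"""kNN graph construction, Moran's I on graphs, and the embedding-conservation score.

Moran's I over a cell-embedding kNN graph measures whether a gene's expression
varies smoothly across the embedding (values near 1), is arranged at random
(values near -1/(N-1), i.e. about 0), or alternates between neighbors (negative).
The conservation score of an integrated embedding is the mean Moran's I over a
set of highly variable genes, rescaled from [-1, 1] to [0, 1]; embeddings that
retain fine biological structure score high, over-integrated or shuffled
embeddings score near 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from . import preprocess
from ._utils import as_dense


@dataclass
class NeighborGraph:
    """Symmetric nonnegative weight matrix over cells with zero diagonal."""

    weights: sp.csr_matrix
    k: int
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def validate(self) -> None:
        W = self.weights
        if (abs(W - W.T) > 1e-12).nnz:
            raise ValueError("weight matrix is not symmetric")
        if np.any(W.diagonal() != 0):
            raise ValueError("weight matrix has nonzero diagonal")
        if self.total_weight <= 0:
            raise ValueError("graph has no edges")


@dataclass
class ConservationResult:
    per_gene_I: np.ndarray
    genes: list
    mean_I: float
    score: float

    @property
    def g(self) -> int:
        return len(self.per_gene_I)


def knn_graph(embedding: np.ndarray, k: int = 15, weighted: bool = False) -> NeighborGraph:
    """Union-symmetrized kNN graph (edge if either node lists the other among
    its k nearest by Euclidean distance); binary weights by default.

    Ties in distance are broken by node index (deterministic). With
    ``weighted=True`` edges carry a Gaussian kernel of the distance with
    per-node bandwidth equal to the k-th neighbor distance.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("embedding must be 2-D (cells x dims)")
    if not np.isfinite(X).all():
        raise ValueError("embedding contains non-finite coordinates")
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of points n={n}")

    if n <= 2048:
        # exact, with index tie-break via stable double argsort
        sq = (X ** 2).sum(axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
        np.fill_diagonal(d2, np.inf)
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        dist = np.sqrt(np.take_along_axis(d2, idx, axis=1))
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        dist, idx = nn.kneighbors(X)
        dist, idx = dist[:, 1:], idx[:, 1:]

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    if weighted:
        bw = np.maximum(dist[:, -1], 1e-12)
        vals = np.exp(-(dist.ravel() ** 2) / (2 * np.repeat(bw, k) ** 2))
    else:
        vals = np.ones(n * k)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    return NeighborGraph(weights=A.tocsr(), k=k)


def morans_i(x: np.ndarray, graph: NeighborGraph) -> float:
    """Moran's I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2."""
    x = np.asarray(x, dtype=float).ravel()
    W = graph.weights
    if x.size != W.shape[0]:
        raise ValueError("value vector length does not match graph size")
    z = x - x.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValueError("undefined autocorrelation: zero-variance values")
    return float(graph.n / graph.total_weight * (z @ (W @ z)) / denom)


def morans_i_genes(X, graph: NeighborGraph, chunk: int = 256) -> np.ndarray:
    """Vectorized Moran's I for each column of a (cells x genes) matrix.

    Zero-variance columns yield NaN rather than raising.
    """
    W = graph.weights
    n = graph.n
    total_w = graph.total_weight
    n_genes = X.shape[1]
    out = np.empty(n_genes)
    for start in range(0, n_genes, chunk):
        block = as_dense(X[:, start:start + chunk])
        Z = block - block.mean(axis=0, keepdims=True)
        num = np.einsum("ij,ij->j", Z, W @ Z)
        den = np.einsum("ij,ij->j", Z, Z)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[start:start + chunk] = np.where(den > 0, n / total_w * num / den, np.nan)
    return out


def conservation_score(adata, embedding: np.ndarray, batch_key: str = "sample",
                       g: int = 1000, k: int = 15, layer: str = "lognorm",
                       min_cells_expressed: int = 3) -> ConservationResult:
    """Moran's I conservation of an integrated embedding.

    Selects ``g`` batch-aware HVGs from the normalized expression, computes
    per-gene Moran's I on the embedding's kNN graph, and reports
    ``score = (mean I + 1) / 2`` in [0, 1].
    """
    X = adata.layers[layer]
    expressed = np.asarray((X > 0).sum(axis=0)).ravel() >= min_cells_expressed
    pool = adata[:, expressed]
    n_avail = int(expressed.sum())
    if n_avail < g:
        warnings.warn(f"only {n_avail} eligible genes (< g={g}); using all")
        g = n_avail
    hvgs = preprocess.hvg_batch(pool, n_top=g, batch_key=batch_key, layer=layer)
    gidx = [pool.var_names.get_loc(h) for h in hvgs]
    graph = knn_graph(np.asarray(embedding, dtype=float), k=k)
    per_gene = morans_i_genes(pool.layers[layer][:, gidx], graph)
    mean_I = float(per_gene[np.isfinite(per_gene)].mean())
    return ConservationResult(per_gene_I=per_gene, genes=hvgs,
                              mean_I=mean_I, score=(mean_I + 1.0) / 2.0)
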
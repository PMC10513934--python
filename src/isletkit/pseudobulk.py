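"""Fine (metacell-style) and metadata pseudobulks, state clustering on gene-program
scores, pruned cluster-graph connectivity, and weighted-kNN label transfer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, ward

from .graph import NeighborGraph
from ._utils import as_dense


@dataclass
class PseudobulkMatrix:
    profiles: np.ndarray          # clusters x genes
    sizes: np.ndarray             # cells per cluster
    kind: str                     # "fine" (mean of lognorm) | "metadata" (summed counts)
    keys: pd.DataFrame            # grouping metadata per cluster
    cell_to_cluster: np.ndarray = field(default=None)

    @property
    def n_clusters(self) -> int:
        return self.profiles.shape[0]


@dataclass
class StatePartition:
    level: str                    # "coarse" | "fine"
    labels: np.ndarray            # per cell
    provenance: dict


def leiden_partition(graph: NeighborGraph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Seeded Leiden community detection (RB-configuration modularity) on the cell graph."""
    import igraph as ig
    import leidenalg

    W = graph.weights.tocoo()
    if W.shape[0] == 0:
        raise ValueError("empty graph")
    mask = W.row < W.col
    edges = list(zip(W.row[mask].tolist(), W.col[mask].tolist()))
    g = ig.Graph(n=W.shape[0], edges=edges)
    g.es["weight"] = W.data[mask].tolist()
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


def fine_pseudobulk(norm_expr, labels) -> PseudobulkMatrix:
    """Mean log1p-normalized expression per cluster ('metacell' profiles)."""
    labels = np.asarray(labels)
    if labels.size != norm_expr.shape[0]:
        raise ValueError("labels must cover all cells")
    clusters = pd.unique(labels)
    profiles, sizes = [], []
    for c in clusters:
        m = labels == c
        profiles.append(np.asarray(norm_expr[m].mean(axis=0)).ravel())
        sizes.append(int(m.sum()))
    return PseudobulkMatrix(
        profiles=np.vstack(profiles), sizes=np.asarray(sizes), kind="fine",
        keys=pd.DataFrame({"cluster": clusters}), cell_to_cluster=labels,
    )


def metadata_pseudobulk(counts, keys: pd.DataFrame) -> PseudobulkMatrix:
    """Raw counts summed per unique metadata key combination (no log transform)."""
    keys = keys.reset_index(drop=True)
    if len(keys) != counts.shape[0]:
        raise ValueError("keys must have one row per cell")
    group_ids, group_keys = pd.factorize(pd.MultiIndex.from_frame(keys))
    X = counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(counts)
    ind = sp.csr_matrix(
        (np.ones(len(group_ids)), (group_ids, np.arange(len(group_ids)))),
        shape=(len(group_keys), len(group_ids)),
    )
    profiles = np.asarray((ind @ X).todense())
    sizes = np.bincount(group_ids, minlength=len(group_keys))
    return PseudobulkMatrix(
        profiles=profiles, sizes=sizes, kind="metadata",
        keys=pd.DataFrame(list(group_keys), columns=keys.columns),
        cell_to_cluster=group_ids,
    )


def gp_state_clustering(pb_gp_scores: np.ndarray, pb: PseudobulkMatrix,
                        linkage_cut: float | None = None, level: str = "fine",
                        standardize: bool = True, max_states: int = 10) -> StatePartition:
    """Cluster fine pseudobulks on their gene-program score vectors into cell states.

    Ward linkage on Euclidean distance over z-scored GP scores (so no single
    program's score scale dominates). With ``linkage_cut`` given, the dendrogram
    is cut at that absolute height; by default the number of states is chosen by
    silhouette over 2..``max_states`` candidate cuts, preferring the finest
    partition whose silhouette is within 80% of the best — fine states are the
    goal, so granularity is favored as long as cluster cohesion holds (the
    automated analogue of a by-eye dendrogram cut). Cells inherit their
    pseudobulk's state.
    """
    from sklearn.metrics import silhouette_score

    S = as_dense(pb_gp_scores)
    if standardize and S.shape[0] > 1:
        sd = S.std(axis=0)
        S = (S - S.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if S.shape[0] != pb.n_clusters:
        raise ValueError("one GP-score row per pseudobulk required")
    cut: float | int
    if S.shape[0] == 1:
        state_of_pb = np.zeros(1, dtype=int)
        cut = 0.0
    elif linkage_cut is not None:
        Z = ward(S)
        cut = linkage_cut
        if cut <= 0:
            state_of_pb = np.arange(S.shape[0])
        else:
            state_of_pb = fcluster(Z, t=cut, criterion="distance") - 1
    else:
        Z = ward(S)
        sils = {}
        for ncl in range(2, min(max_states, S.shape[0] - 1) + 1):
            labels = fcluster(Z, t=ncl, criterion="maxclust") - 1
            if len(np.unique(labels)) >= 2:
                sils[ncl] = silhouette_score(S, labels)
        if not sils:
            state_of_pb = np.zeros(S.shape[0], dtype=int)
            cut = 1
        else:
            best = max(sils.values())
            cut = max(n for n, s in sils.items() if s >= 0.80 * best)
            state_of_pb = fcluster(Z, t=cut, criterion="maxclust") - 1
    cluster_index = {c: i for i, c in enumerate(pb.keys["cluster"])}
    cell_states = np.array([state_of_pb[cluster_index[c]] for c in pb.cell_to_cluster])
    return StatePartition(
        level=level, labels=cell_states,
        provenance={"method": "ward_on_gp_scores", "cut": float(cut),
                    "standardized": bool(standardize),
                    "n_states": int(len(np.unique(state_of_pb)))},
    )


def cluster_connectivity(graph: NeighborGraph, states, prune_threshold: float = 0.0) -> pd.DataFrame:
    """Configuration-model-normalized inter-state connectivity, pruned and clipped to [0,1].

    connectivity(s,t) = observed inter-state edge weight / expected weight under a
    degree-preserving null E[s,t] = vol_s * vol_t / (2 * total_edge_weight).
    """
    states = np.asarray(states)
    labels = pd.unique(states)
    counts = {s: int((states == s).sum()) for s in labels}
    if any(v == 0 for v in counts.values()):
        raise ValueError("state with no cells")
    W = graph.weights
    deg = np.asarray(W.sum(axis=1)).ravel()
    total = W.sum() / 2.0
    ind = np.vstack([(states == s).astype(float) for s in labels])
    obs_off = ind @ W @ ind.T
    vol = ind @ deg
    conn = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            expected = vol[i] * vol[j] / (2.0 * total) if total > 0 else 0.0
            c = obs_off[i, j] / expected if expected > 0 else 0.0
            c = min(c, 1.0)
            if c < prune_threshold:
                c = 0.0
            conn[i, j] = conn[j, i] = c
    return pd.DataFrame(conn, index=labels, columns=labels)


def label_transfer(ref_embedding, ref_labels, query_embedding, k: int = 15,
                   uncertainty_threshold: float = 0.75) -> pd.DataFrame:
    """Weighted-kNN label transfer with an uncertainty threshold.

    For each query cell the k nearest reference cells (Euclidean) vote with
    Gaussian-kernel weights (bandwidth = distance to the k-th neighbor); the
    winning label's vote share defines uncertainty = 1 - share, and cells with
    uncertainty above the threshold are reported as "unassigned".
    """
    from sklearn.neighbors import NearestNeighbors

    R = np.asarray(ref_embedding, dtype=float)
    Q = np.asarray(query_embedding, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if k > R.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {R.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(R)
    dist, idx = nn.kneighbors(Q)
    bw = np.maximum(dist[:, -1], 1e-12)
    wts = np.exp(-(dist ** 2) / (2 * bw[:, None] ** 2))

    uniq = pd.unique(ref_labels)
    lab_idx = {l: i for i, l in enumerate(uniq)}
    votes = np.zeros((Q.shape[0], len(uniq)))
    neigh_lab = np.vectorize(lab_idx.get)(ref_labels[idx])
    for j in range(k):
        np.add.at(votes, (np.arange(Q.shape[0]), neigh_lab[:, j]), wts[:, j])
    votes /= votes.sum(axis=1, keepdims=True)
    win = votes.argmax(axis=1)
    share = votes[np.arange(Q.shape[0]), win]
    uncertainty = 1.0 - share
    labels = np.asarray(uniq)[win].astype(object)
    labels[uncertainty > uncertainty_threshold] = "unassigned"
    return pd.DataFrame({"label": labels, "uncertainty": uncertainty})
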
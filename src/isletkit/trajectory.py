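"""Continuous disease-process score from graph-diffusion condition densities.

Healthy- and diseased-sample indicator vectors are normalized by group size and
smoothed by a t-step random walk on the cell kNN graph; the per-cell score
healthy / (healthy + diseased) is a continuous coordinate from the most
diseased (0) to the most healthy (1) region of the embedding, determined by the
cell's neighborhood rather than its own sample label. Per-dataset scores are
averaged so no single dataset dominates the pooled analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import NeighborGraph


@dataclass
class ProcessScore:
    score: np.ndarray                 # per cell in [0, 1]; 1 = most healthy
    per_dataset: pd.DataFrame         # per-dataset component scores (NaN where absent)
    t_steps: int
    k: int


def condition_density(graph: NeighborGraph, indicators: dict, t_steps: int = 3) -> dict:
    """t-step random-walk smoothed density for each condition indicator.

    ``indicators`` maps condition name -> boolean per-cell membership. Each
    indicator is divided by its group size (so unbalanced designs do not bias
    downstream ratios) and diffused with the row-stochastic transition matrix of
    the graph: density_c = P^t (indicator_c / n_c).
    """
    W = graph.weights
    deg = np.asarray(W.sum(axis=1)).ravel()
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
    P = sp.diags(inv_deg) @ W
    out = {}
    for name, ind in indicators.items():
        ind = np.asarray(ind, dtype=float).ravel()
        n_c = ind.sum()
        if n_c == 0:
            raise ValueError(f"condition {name!r} has zero cells")
        d = ind / n_c
        for _ in range(t_steps):
            d = P @ d
        out[name] = np.asarray(d).ravel()
    return out


def process_score(graph: NeighborGraph, condition, dataset_labels=None,
                  healthy_label: str = "healthy", diseased_label: str = "diseased",
                  t_steps: int = 3) -> ProcessScore:
    """Per-cell healthy/(healthy+diseased) diffusion-density score, averaged over datasets.

    When ``dataset_labels`` is given, densities are computed within each dataset
    that contains both conditions (using that dataset's cells as indicator
    support on the shared graph) and the final score is the mean across those
    datasets. Cells where both densities vanish get 0.5.
    """
    condition = np.asarray(condition)
    n = graph.n
    if dataset_labels is None:
        dataset_labels = np.zeros(n)
    dataset_labels = np.asarray(dataset_labels)

    cols = {}
    for d in pd.unique(dataset_labels):
        in_d = dataset_labels == d
        h = in_d & (condition == healthy_label)
        s = in_d & (condition == diseased_label)
        if h.sum() == 0 or s.sum() == 0:
            continue
        dens = condition_density(graph, {"healthy": h, "diseased": s}, t_steps=t_steps)
        tot = dens["healthy"] + dens["diseased"]
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[str(d)] = np.where(tot > 0, dens["healthy"] / np.maximum(tot, 1e-300), 0.5)
    if not cols:
        raise ValueError("no dataset contains both healthy and diseased cells")
    per_dataset = pd.DataFrame(cols)
    score = per_dataset.mean(axis=1).to_numpy()
    return ProcessScore(score=np.clip(score, 0.0, 1.0), per_dataset=per_dataset,
                        t_steps=t_steps, k=graph.k)
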
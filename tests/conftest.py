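"""Shared fixtures: small synthetic atlases and derived products, built once."""

import collections

import numpy as np
import pytest
from sklearn.decomposition import PCA

import isletkit as ik


def prepare_beta(adata, truth, seed=0, n_pcs=15, k=15):
    """Normalize, subset to beta singlets, and build kNN graphs on both the
    simulated integrated embedding (latent) and an unintegrated PCA embedding."""
    adata = adata[~adata.obs.is_empty.values].copy()
    adata = ik.normalize_log1p(adata)
    beta = adata[(adata.obs.true_cell_type == "beta").values
                 & ~adata.obs.is_doublet.values].copy()
    hv = ik.hvg_batch(beta, n_top=min(2000, beta.n_vars))
    X = np.asarray(beta.layers["lognorm"][:, [beta.var_names.get_loc(h) for h in hv]].todense())
    emb = PCA(n_pcs, random_state=seed, svd_solver="full").fit_transform(X - X.mean(0))
    latent = np.asarray(beta.obsm["X_latent"], dtype=float)
    return {"adata": adata, "beta": beta, "hvgs": hv, "embedding": emb,
            "pca_graph": ik.knn_graph(emb, k=k),
            "graph": ik.knn_graph(latent, k=k), "latent": latent}


def truth_program_sets(truth):
    progs = collections.defaultdict(list)
    for g, pid in truth.program_membership.items():
        progs[pid].append(g)
    return dict(progs)


@pytest.fixture(scope="session")
def small_atlas():
    """2 datasets x 2 samples x 300 cells, 600 genes; fast unit-test workhorse."""
    cfg = ik.SyntheticConfig(n_datasets=2, samples_per_dataset=2, cells_per_sample=300,
                             n_genes=600, n_empty_droplets=80, seed=5)
    adata, truth = ik.generate_atlas(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def healthy_atlas():
    """Default-size all-healthy atlas (6,000 cells, 2,000 genes, 5 programs, 4 states)."""
    cfg = ik.SyntheticConfig(seed=11, disease_conditions=("healthy",) * 6)
    adata, truth = ik.generate_atlas(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def healthy_beta(healthy_atlas):
    cfg, adata, truth = healthy_atlas
    return prepare_beta(adata, truth, seed=11), truth


@pytest.fixture(scope="session")
def diseased_atlas():
    """Default study design: 3 datasets x (healthy, diseased) samples."""
    cfg = ik.SyntheticConfig(seed=7)
    adata, truth = ik.generate_atlas(cfg)
    return cfg, adata, truth
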
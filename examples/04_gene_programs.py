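"""Discover gene programs with bias-corrected Moran's I.

Moran's I on the cell-embedding kNN graph flags genes whose expression varies
smoothly across cell states, but it is biased downward for sparsely detected
genes. The correction regresses a baseline trend (lowest-I genes per detection
bin) of I on log10(cells expressing) and keeps the residual; top genes are then
clustered on fine-pseudobulk profiles into coexpression programs.
"""

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

import isletkit as ik

cfg = ik.SyntheticConfig(seed=0, disease_conditions=("healthy",) * 6,
                         cells_per_sample=600)
adata, truth = ik.generate_atlas(cfg)
adata = ik.normalize_log1p(adata[~adata.obs.is_empty.values].copy())
beta = adata[(adata.obs.true_cell_type == "beta").values
             & ~adata.obs.is_doublet.values].copy()

hvgs = ik.hvg_batch(beta, n_top=2000)
X = np.asarray(beta.layers["lognorm"][:, [beta.var_names.get_loc(h) for h in hvgs]].todense())
emb = PCA(15, random_state=0, svd_solver="full").fit_transform(X - X.mean(0))
graph = ik.knn_graph(emb, k=15)

n_expr = np.asarray((beta.layers["lognorm"] > 0).sum(axis=0)).ravel()
cand = np.where(n_expr >= 10)[0]
I = ik.morans_i_genes(beta.layers["lognorm"][:, cand], graph)
cm = ik.corrected_morans_i(I, n_expr[cand], genes=beta.var_names[cand].to_numpy(),
                           high_expr_cutoff=0.40 * beta.n_obs)
top = cm.top_genes(top_k=200)
print(f"baseline slope of I on log10(n expressing): {cm.slope:.4f}")

fine = ik.leiden_partition(graph, resolution=20.0, seed=0)
pb = ik.fine_pseudobulk(beta.layers["lognorm"], fine)
tidx = [beta.var_names.get_loc(g) for g in top]
programs = ik.cluster_gene_programs(top, pb.profiles[:, tidx].T)
print(f"{len(programs)} programs of sizes {[len(p.genes) for p in programs]}")

pred = {g: p.id for p in programs for g in p.genes}
genes = list(truth.program_membership)
ari = adjusted_rand_score([truth.program_membership[g] for g in genes],
                          [pred.get(g, "none") for g in genes])
print(f"gene-to-program assignment ARI vs planted truth: {ari:.2f}")
# ARI near 1 means the five planted coexpression modules were recovered as
# separate programs despite NB noise and ambient contamination.
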
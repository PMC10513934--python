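# isletkit

Analysis toolkit for cross-condition mouse pancreatic islet scRNA-seq atlases.
It implements the bespoke computational procedures such an atlas needs once the
expression matrices and an integrated embedding exist: scoring embedding quality
without annotations, separating ambient from endogenous signal, discovering
gene programs free of detection bias, defining β-cell states, placing each cell
on a continuous healthy→diseased coordinate, and calling markers and
differentially expressed genes that are conserved across datasets.

## Who it is for

Computational biologists integrating islet (or other heterogeneous-tissue)
scRNA-seq across multiple datasets and disease models — e.g. autoimmune (NOD),
leptin-receptor-deficient (db/db) and chemically induced (mSTZ) diabetes models
— who need the analysis layer between integration and biology. Everything is
testable at desk scale against a built-in synthetic atlas generator with
complete ground truth.

## The statistics at the core

**Moran's I conservation.** For a cell embedding with kNN graph weights
*w<sub>ij</sub>*, a gene's spatial autocorrelation is

I = (N/W) · Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²,  I ∈ [−1, 1].

The conservation score of an embedding is `score = (mean I over g HVGs + 1)/2`
(g = 1,000 by default), in [0, 1]: an embedding that retains biological
variation scores high, a shuffled or over-integrated one scores ≈ 0.5.

**Bias-corrected Moran's I.** I is biased downward for genes detected in few
cells. Genes unlikely to be truly variable (the five lowest-I genes in each of
20 equal-frequency detection bins, after excluding ubiquitously expressed
genes) define a baseline OLS trend of I on log₁₀(cells expressing); the
corrected score is the residual. Top-residual genes clustered on fine-pseudobulk
("metacell") profiles yield coexpression gene programs (GPs).

**Disease process score.** Healthy/diseased sample indicators, normalized by
group size and diffused t steps (default 3) with the row-stochastic transition
matrix of the cell kNN graph, give densities h and d; the per-cell score
h/(h+d) ∈ [0, 1] (1 = most healthy region) is averaged across datasets.

**NB-GLM differential expression.** Per gene, a negative-binomial GLM with log
link and size factors as exposure offset (dispersion by method of moments on
the residuals, iterated), a two-sided Wald test on the coefficient of interest,
and log2-scale fold changes. Used for trajectory DGE, sex differences, and
pseudobulk cell-type markers; cross-dataset conserved markers use cell-level
Welch tests with an all-datasets-vs-all-groups rule.

## Worked example

```python
import isletkit as ik

cfg = ik.SyntheticConfig(seed=0)          # 3 datasets x 2 samples, ~6,000 cells
adata, truth = ik.generate_atlas(cfg)

report = ik.run_pipeline({"seed": 0, "simulate": {}, "out_dir": "out"})
print(report["conservation_score"], report["n_programs"],
      report["frac_states_pure"], report["n_deg"])
```

which prints (seed 0):

```
0.5733709010760814 7 0.8 82
```

meaning: the unintegrated PCA embedding retains moderate biological structure
(conservation 0.573 on the 0–1 scale); seven gene programs were discovered in
β-cells (the five planted coexpression modules plus trajectory-driven gene
groups); 80% of the fine β-cell states are condition-pure at the 0.8 level; and
82 genes change significantly (FDR < 0.05, |log2FC| > 1, relative expression
> 0.2) along the inferred healthy→diseased trajectory. The same steps are available as a CLI:
`isletkit simulate|qc|ambient|integrate-eval|run ...`.

The `examples/` directory has one short narrative script per capability
(simulation and IO, conservation scoring, ambient detection, gene programs,
trajectory DGE, conserved markers and label transfer); each prints the numbers
it computes and what they mean.

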
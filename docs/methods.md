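# Methods

This note documents the models and procedures implemented in isletkit, the
assumptions behind them, the defaults that matter, what the synthetic atlas
generator does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Scope and data model

isletkit operates downstream of dataset integration: its inputs are raw count
matrices (CellRanger-dialect MTX bundles or h5ad), per-cell metadata (sample,
dataset, condition, sex, cell type), and a low-dimensional cell embedding.
Integration model training itself (scVI/scArches-class methods), ambient
*correction*, doublet *detection* and empty-droplet probabilistic calling are
out of scope; where an analysis needs their outputs (an integrated embedding,
doublet flags), they are treated as inputs. In-memory, datasets are
`anndata.AnnData` objects: raw counts in `X`, per-sample log1p-normalized
expression in `layers["lognorm"]`, size factors in `obs["size_factor"]`, and an
integrated embedding (when available) in `obsm["X_latent"]`.

## Preprocessing

Cells are filtered on expressed genes, total counts (both tails) and
mitochondrial fraction (gene-name prefix, default `mt-`); thresholds are
configuration values, chosen per dataset by the analyst, not inferred.

Normalization is per sample. The default ("total") size factor is the cell's
total divided by the sample median total, so that after division every cell's
total equals the sample median — the behaviour downstream contracts assume. A
median-of-ratios option (per-sample pseudo-reference over detected genes,
rescaled to geometric mean one within the sample) is provided for datasets with
strong composition effects. Pooling-based deconvolution size factors are
deliberately not reimplemented; per-sample normalization is what the
integration-facing contract requires.

Batch-aware HVG selection ranks genes per batch by variance/mean dispersion
z-scored within 20 equal-frequency mean-expression bins (cell_ranger-flavour
contract), then orders genes by how many batches place them in the per-batch
top-n, breaking ties by median cross-batch rank and then gene index. The
procedure is deterministic; constant genes rank last.

## Moran's I conservation

The embedding-quality score computes g = 1,000 batch-aware HVGs on expression,
Moran's I for each on the embedding's kNN graph (k = 15 by default; the graph
is union-symmetrized, binary, zero-diagonal), and reports (mean I + 1)/2.
Binary weights were chosen over kernel weights because they match the classical
Moran's I convention and admit exact closed-form test cases (alternating path
= −1; permutation mean = −1/(N−1)); kernel weights are available behind a flag.
Genes expressed in fewer than 3 cells are excluded (their I is noise). k is not
dictated by the metric's definition; 15 is the package default and exposed.

## Ambient genes

The ambient profile of a sample is the gene-proportion vector of pooled
droplets with < 100 total counts. Per sample, a proportion threshold is placed
at the target-th ranked gene (ties broken by index) and sets are pooled across
samples as unions — a small set (≈ 20 genes/sample) and a permissive set
(≈ 100). Target-size selection replaces the original interactive
threshold-by-inspection heuristic because it is deterministic and testable; the
"cumulative ambient proportion saturation" judgment is approximated by the
larger target.

Relative expression of a gene in a cell type: cluster means (high-resolution
Leiden, resolution 2) on the **linear** normalized scale are maxabs-scaled
across clusters per gene; a gene's value for a cell type is the maximum over
clusters whose modal cell-type label exceeds 50%. The linear scale matters:
log1p compresses the contrast between a hormone's endogenous expression
(hundreds of counts) and its ambient level (≈ ten counts) from ~50:1 to ~2:1,
which would defeat the 0.2/0.5/0.7 cutoffs used downstream. Known doublets are
excluded from the clustering because mixed profiles inflate a type's apparent
relative expression. Ambient genes are grouped by hierarchical clustering
(Pearson distance, average linkage, k = max(2, ⌈n/5⌉) groups) and a group is
flagged non-β-ambient when its best relative expression in β clusters is below
the cutoff (default 0.5).

## Gene programs

Candidate genes (expressed in ≥ a minimum number of cells, non-β-ambient genes
removed) get Moran's I on the β-cell embedding graph. The sparsity-bias
correction fits OLS of I on log₁₀(n cells expressing) over baseline genes: the
five lowest-I genes per each of 20 equal-frequency detection bins, after
excluding genes expressed in ≥ 40% of cells (those deviate upward for
biological reasons). The corrected score is the residual. OLS on the log scale
was chosen for closed-form residuals and a monotone smooth trend; a lowess
option exists. Whether to log-transform the regressor is exposed
(`log_transform`), as is the selection rule for "top" genes (`top_k`, default
here 200, or an absolute threshold) — both recorded in provenance.

Programs are hierarchical clusters (1 − Pearson r, average linkage) of the
selected genes over fine-pseudobulk profiles; the cut defaults to half the
maximum merge height (the original cut was chosen by eye from a heat map) and
programs below 5 genes are dropped. Per-cell GP activity uses control-matched
scoring: mean expression over the set minus mean over seeded random controls
drawn from the same 25 mean-expression bins (50 per bin), excluding set
members; when a tiny gene universe exhausts the shared bins the controls fall
back to all non-set genes (with a warning). Winsorized [0,1] normalization
sets the scaling range after dropping the 20 highest and lowest cells and clips.

Conserved healthy-heterogeneity groups repeat the per-sample corrected-I
selection (baseline exclusion at 30% of cells), keep genes selected in **all**
samples, and cluster them with the per-gene distance equal to the **maximum**
across samples of the per-sample correlation distance on fine pseudobulks —
so a group must cohere in every sample.

Explained variance: 50 PCs on HVG expression; each PC regressed on the GP score
matrix (rank-deficient designs pruned by QR); total EV = Σ R²ₖ·varratioₖ. The
null repeats the procedure with size-matched random gene groups (default 100
draws) and the one-sided empirical p is (1 + #{null ≥ obs})/(1 + n_rand).

## Pseudobulks and β-cell states

Fine pseudobulks are Leiden clusters at high resolution (default 20) with
profiles = mean log1p-normalized expression; metadata pseudobulks sum raw
counts per metadata key combination (no log). GP scores averaged within fine
pseudobulks are z-scored per program (so no single program's score scale
dominates) and Ward-clustered. The dendrogram cut, chosen visually in the
original workflow, is automated: candidate cuts at 2..10 clusters are compared
by silhouette and the finest partition within 80% of the best silhouette is
taken — fine states are the goal, so granularity is favored as long as cluster
cohesion holds; an absolute height cut can be forced. State-graph connectivity is
observed inter-state edge weight over the configuration-model expectation
vol·vol′/(2·total), clipped to [0,1], pruned below a threshold — a deliberately
simple surrogate for partition-based graph abstraction.

Label transfer uses weighted kNN in a shared embedding: Gaussian kernel with
per-query bandwidth equal to the k-th neighbor distance, label = argmax of the
vote share, uncertainty = 1 − share, cells above uncertainty 0.75 reported as
"unassigned".

## Disease-process score

Condition indicators divided by group size (so unbalanced designs do not bias
the ratio) are diffused t = 3 steps with P = D⁻¹W; score = h/(h+d), 0/0 → 0.5;
per-dataset scores (datasets containing both conditions) are averaged. The
t-step random walk replaces heat-kernel graph filtering: it is dependency-free
and preserves the same qualitative contract (kNN-graph-smoothed sample
likelihood); equivalence with the original filter is not claimed — the
normalization-and-averaging contract plus gradient-recovery testing is what is
reproduced. Small t keeps the score local; large t mixes toward the
degree-stationary distribution and flattens the gradient.

## Differential expression

One NB-GLM core (statsmodels fitting engine; Poisson initialization,
method-of-moments dispersion on residuals iterated twice, dispersion floor
1e−8, two-sided Wald, coefficient/ln 2 reported as log2 FC) stands behind the
trajectory, sex-difference and pseudobulk marker analyses, replacing the two
external GLM stacks the original workflow used. Degenerate fits (SE < 1e−12,
non-convergence, all-zero genes) are flagged with p = 1 and excluded from BH
adjustment, mirroring the "extremely small coefficient SD" exclusion rule.
Null calibration (type-I error ≈ 0.05) and slope recovery are enforced by the
acceptance tests.

Selection rules are pure functions of statistics and thresholds: trajectory
DEGs (FDR < 0.05, |log2FC| > 1, relative expression > 0.2, 5%-expression
prefilter per condition); conserved state markers (Welch FDR < 0.1 and
logFC > 0 in all of a state's datasets against all other states' groups,
dataset included for a state when ≥ 10% of any of its samples' cells are in the
state — the original proportion was unquantified; ranked by minimal logFC;
relative expression ≥ 0.7); one-vs-rest cell-type markers from a joint NB-GLM
with contrasts (FDR < 0.05, log2FC > 1.5 against every other type); conserved
condition genes (pass FDR < 0.25 and logFC > 0.5 in ≥ ⌈half⌉ of datasets, 10%
expression rule per dataset). The reporting convention for multi-comparison
logFC: 0 when the comparisons disagree in sign, otherwise the signed smallest
absolute logFC; the maximum adjusted p across comparisons accompanies it.
Metadata pseudobulks enter the GLM as raw sums with log-total offsets (a count
model needs counts); a flag can mimic summing normalized values instead.

## Synthetic atlas generator

The generator is the package's test bed and defines its study conditions:
3 datasets × 2 samples (one healthy, one diseased) × 1,000 cells over 2,000
genes by default. Per cell, a logit vector (baseline ~ N(0, 0.8)) accumulates:
cell-type marker boosts (+5; one β-like type at 55% prevalence); hormone-like
ambient-driver boosts (+8 in a non-β home type, ≈ 13% of that type's
transcriptome — the hormone regime); state-marker boosts (+2.5); program
activities (five planted programs, each active in two of four β states with
distinct state patterns, activity 1.4·pattern + N(0, 0.5)); disease-process
loadings (40 genes at ±2.5·x — matching the observation that disease
trajectories in these models involve large coordinated expression shifts);
sex-linked genes (3, male-only); per-dataset batch offsets (N(0, 0.3)).
Counts are NB-sampled (per-gene dispersion log-normal around 0.3) around
μ = libsize·((1−af)·softmax(logits) + af·ambient), af = 0.10, with the ambient
profile 65% on the drivers and 35% on the sample's mean cell profile. Doublets
(3%) are NB draws around the sum of two parents' means; empty droplets (300 per
sample) are multinomial draws of 10–79 counts from the ambient profile, so the
< 100-count rule separates them from real cells (library sizes are floored at
4× that margin).

The disease gradient is a real path in expression space: a diseased-state cell
at process x interpolates its state-marker and program effects between a
healthy origin state (x = 0) and its diseased target state (x = 1), with
x ~ U(0.2, 1) — diseased samples in the emulated severe models retain no
fully-healthy β cells, so the continuum starts above the healthy pole. Healthy
states have process exactly 0. In an all-healthy design every state is a
healthy state (no gradient), which is the configuration used to validate
4-state and marker recovery cleanly.

The generator's latent coordinates (type centers, program activities, process
axis) are stored as `obsm["X_latent"]` and double as the *simulated integrated
embedding*: analyses that in production consume an integration model's latent
space consume this embedding in simulation, while the embedding-evaluation
stage still scores the unintegrated PCA embedding. What the generator does
**not** emulate: transcriptome-wide regulatory structure, UMI chemistry and
error models, realistic gene-length/GC effects, spliced/unspliced counts, and
cross-dataset technology differences beyond additive log-scale batch offsets.
Passing tests therefore demonstrate correctness of the procedures under a
faithful low-dimensional generative model, not performance on arbitrary real
data.

## Problem sizes and determinism

Desk-scale defaults were chosen so the full pipeline (~6,000 cells, 2,000
genes) and every recovery analysis complete quickly on a single CPU: explained
variance uses 100 null draws (10–20 inside the pipeline), NB-GLM calibration
uses 2,000 genes at n = 300 and slope recovery at n = 1,000. All randomness
flows from one seed through named SHA-256-derived substreams, so outputs are
byte-identical across runs; every output TSV carries a provenance header with
stage parameters and a config hash.

## Known limitations

- The PCA embedding is an unintegrated stand-in; with strong batch effects,
  batch-driven gene groups can reach high corrected Moran's I on it. This is a
  property of unintegrated embeddings, not of the selection statistic.
- The silhouette-chosen state cut optimizes compactness of GP-score profiles;
  states differing only in features orthogonal to the discovered programs will
  not separate.
- The configuration-model connectivity surrogate ignores degree-degree
  correlations and is not a replacement for the original partition-based
  abstraction method.
- Method-of-moments NB dispersion is per-gene with no shrinkage across genes;
  with very few cells per group (small pseudobulk designs) the Wald test can be
  anticonservative.
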
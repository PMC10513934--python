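"""Synthetic multi-dataset islet-like scRNA-seq atlas with complete ground truth.

The generator emulates the structure of a cross-condition islet atlas: several
datasets, each with several samples; discrete endocrine-like cell types with a
dominant beta-like type; beta-cell states that activate distinct combinations of
planted coexpression programs; a continuous healthy-to-diseased gradient carried
by the beta-like type; per-sample ambient contamination whose profile is
dominated by a few hormone-like genes; empty droplets; doublets; sex-linked
genes; and per-dataset batch offsets.

Counts are negative-binomially sampled around
``mu = libsize * ((1 - ambient_fraction) * softmax(logits) + ambient_fraction * ambient_profile)``
with per-gene dispersion, so every downstream stage (normalization, ambient
detection, Moran's I gene selection, program discovery, state clustering,
trajectory DGE, marker calling) can be validated against known truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmwrite

from ._utils import substream, check_gene_lists_disjoint

BETA_TYPE = "beta"


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic atlas.

    Defaults describe the desk-scale study: 3 datasets x 2 samples x 1,000
    cells over 2,000 genes, one healthy and one diseased sample per dataset.
    """

    n_datasets: int = 3
    samples_per_dataset: int = 2
    cells_per_sample: int = 1000
    n_genes: int = 2000
    n_celltypes: int = 4
    n_states: int = 4
    n_programs: int = 5
    program_size_range: tuple = (20, 40)
    n_state_markers: int = 5
    n_type_markers: int = 8
    n_process_genes: int = 40
    disease_conditions: tuple = ()  # per-sample labels; default alternates healthy/diseased
    ambient_fraction: float = 0.10
    n_ambient_driver_genes: int = 20
    batch_sd: float = 0.3
    doublet_rate: float = 0.03
    n_empty_droplets: int = 300
    dispersion: float = 0.3
    mean_library_size: float = 2500.0
    min_cell_counts: int = 100
    beta_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self):
        counts = [
            self.n_datasets, self.samples_per_dataset, self.cells_per_sample,
            self.n_genes, self.n_celltypes, self.n_states, self.n_programs,
            self.n_state_markers,
        ]
        if any(c < 1 for c in counts):
            raise SyntheticConfigError("all count parameters must be >= 1")
        if not (0 <= self.ambient_fraction < 1):
            raise SyntheticConfigError("ambient_fraction must be in [0, 1)")
        if self.ambient_fraction + self.doublet_rate >= 1:
            raise SyntheticConfigError("ambient_fraction + doublet_rate must be < 1")
        lo, hi = self.program_size_range
        if lo < 1 or hi < lo:
            raise SyntheticConfigError("invalid program_size_range")
        if not self.disease_conditions:
            n_samples = self.n_datasets * self.samples_per_dataset
            self.disease_conditions = tuple(
                "healthy" if i % 2 == 0 else "diseased" for i in range(n_samples)
            )
        if len(self.disease_conditions) != self.n_datasets * self.samples_per_dataset:
            raise SyntheticConfigError(
                "disease_conditions must have one label per sample "
                f"({self.n_datasets * self.samples_per_dataset})"
            )
        bad = set(self.disease_conditions) - {"healthy", "diseased"}
        if bad:
            raise SyntheticConfigError(f"unknown condition labels: {bad}")

    @property
    def n_samples(self) -> int:
        return self.n_datasets * self.samples_per_dataset


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth of the generated atlas (aligned to all droplets)."""

    cell_type: np.ndarray
    state: np.ndarray
    disease_process: np.ndarray
    program_membership: dict        # gene name -> program id
    marker_genes: dict              # state -> gene name list
    type_marker_genes: dict         # cell type -> gene name list
    process_genes: dict             # "up"/"down" -> gene name list
    ambient_genes: list
    sex_genes: list
    latent: np.ndarray
    is_doublet: np.ndarray
    is_empty: np.ndarray

    def to_json(self) -> str:
        payload = {
            "cell_type": self.cell_type.tolist(),
            "state": self.state.tolist(),
            "disease_process": self.disease_process.tolist(),
            "program_membership": self.program_membership,
            "marker_genes": self.marker_genes,
            "type_marker_genes": self.type_marker_genes,
            "process_genes": self.process_genes,
            "ambient_genes": self.ambient_genes,
            "sex_genes": self.sex_genes,
            "latent": self.latent.tolist(),
            "is_doublet": self.is_doublet.tolist(),
            "is_empty": self.is_empty.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            cell_type=np.asarray(d["cell_type"]),
            state=np.asarray(d["state"]),
            disease_process=np.asarray(d["disease_process"], dtype=float),
            program_membership=d["program_membership"],
            marker_genes=d["marker_genes"],
            type_marker_genes=d["type_marker_genes"],
            process_genes=d["process_genes"],
            ambient_genes=d["ambient_genes"],
            sex_genes=d["sex_genes"],
            latent=np.asarray(d["latent"], dtype=float),
            is_doublet=np.asarray(d["is_doublet"], dtype=bool),
            is_empty=np.asarray(d["is_empty"], dtype=bool),
        )


def _allocate_genes(cfg: SyntheticConfig, rng: np.random.Generator):
    """Partition gene indices into planted roles; everything else is background."""
    cursor = 0

    def take(n):
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    type_markers = {t: take(cfg.n_type_markers) for t in range(cfg.n_celltypes)}
    state_markers = {s: take(cfg.n_state_markers) for s in range(cfg.n_states)}
    sizes = np.linspace(*cfg.program_size_range, cfg.n_programs).round().astype(int)
    programs = {p: take(int(sizes[p])) for p in range(cfg.n_programs)}
    ambient_drivers = take(cfg.n_ambient_driver_genes)
    n_up = cfg.n_process_genes // 2
    process_up = take(n_up)
    process_down = take(cfg.n_process_genes - n_up)
    sex_genes = take(3)
    if cursor > cfg.n_genes:
        raise SyntheticConfigError(
            f"planted gene roles need {cursor} genes but n_genes={cfg.n_genes}"
        )
    assert check_gene_lists_disjoint(list(programs.values()))
    return type_markers, state_markers, programs, ambient_drivers, process_up, process_down, sex_genes


# state -> active-program combination; every program active in >= 2 states so
# that program genes are never state-exclusive (state markers are the only
# exclusive genes), and no two programs share the same state pattern (identical
# patterns would make the programs indistinguishable by coexpression)
def _state_program_matrix(n_states: int, n_programs: int) -> np.ndarray:
    from itertools import combinations

    if n_states < 2:
        return np.ones((n_states, n_programs))
    pairs = list(combinations(range(n_states), 2))
    mat = np.zeros((n_states, n_programs))
    for p in range(n_programs):
        for s in pairs[p % len(pairs)]:
            mat[s, p] = 1.0
    return mat


def generate_atlas(config: SyntheticConfig) -> tuple[AnnData, GroundTruth]:
    """Simulate the atlas; returns counts (cells+empty droplets) x genes and full truth.

    The returned AnnData holds raw integer counts in ``X`` with obs columns
    ``sample, dataset, condition, sex, is_doublet, is_empty`` plus the truth
    labels ``true_cell_type, true_state, true_disease_process``.
    """
    cfg = config
    rng = substream(cfg.seed, "synthetic")

    (type_markers, state_markers, programs, ambient_drivers,
     process_up, process_down, sex_genes) = _allocate_genes(cfg, rng)

    gene_names = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    # hormone-like ambient drivers live in non-beta types (round-robin)
    non_beta = [t for t in range(cfg.n_celltypes) if t != 0] or [0]
    driver_type = {g: non_beta[i % len(non_beta)] for i, g in enumerate(ambient_drivers)}

    base = rng.normal(0.0, 0.8, cfg.n_genes)
    planted = np.concatenate([
        np.concatenate(list(type_markers.values())),
        np.concatenate(list(state_markers.values())),
        ambient_drivers, process_up, process_down, sex_genes,
    ])
    base[planted] = rng.normal(-2.0, 0.3, planted.size)

    disp = np.exp(rng.normal(np.log(cfg.dispersion), 0.3, cfg.n_genes))
    disp = np.maximum(disp, 1e-8)

    state_prog = _state_program_matrix(cfg.n_states, cfg.n_programs)
    # with diseased samples present, half the states are healthy-only and half
    # diseased-dominant; in an all-healthy design every state is a healthy state
    if "diseased" in cfg.disease_conditions and cfg.n_states > 1:
        healthy_states = np.arange(cfg.n_states // 2)
        diseased_states = np.setdiff1d(np.arange(cfg.n_states), healthy_states)
    else:
        healthy_states = np.arange(cfg.n_states)
        diseased_states = healthy_states

    batch_offset = rng.normal(0.0, cfg.batch_sd, (cfg.n_datasets, cfg.n_genes))

    type_names = np.array([BETA_TYPE] + [f"type{t}" for t in range(1, cfg.n_celltypes)])
    type_probs = np.full(cfg.n_celltypes, (1 - cfg.beta_fraction) / max(cfg.n_celltypes - 1, 1))
    type_probs[0] = cfg.beta_fraction if cfg.n_celltypes > 1 else 1.0

    blocks_X, obs_rows = [], []
    ct_all, st_all, proc_all, doub_all, empty_all, latent_all = [], [], [], [], [], []

    sample_idx = 0
    for d in range(cfg.n_datasets):
        for s in range(cfg.samples_per_dataset):
            condition = cfg.disease_conditions[sample_idx]
            sample = f"ds{d}_s{s}"
            sex = "male" if sample_idx % 2 == 0 else "female"

            n_cells = cfg.cells_per_sample
            n_doub = int(round(cfg.doublet_rate * n_cells))
            n_sing = n_cells - n_doub

            ctype = rng.choice(cfg.n_celltypes, size=n_sing, p=type_probs)
            is_beta = ctype == 0

            state = np.full(n_sing, -1)
            process = np.zeros(n_sing)
            pool = healthy_states if condition == "healthy" else diseased_states
            state[is_beta] = rng.choice(pool, size=is_beta.sum())
            if condition == "diseased":
                # diseased-state cells span the healthy->diseased gradient uniformly;
                # even the least-stressed cells of a diseased sample are mildly
                # affected, so the continuum starts slightly above the healthy pole
                process[is_beta] = rng.uniform(0.2, 1.0, is_beta.sum())

            logits = np.tile(base, (n_sing, 1)) + batch_offset[d]
            for t, genes in type_markers.items():
                logits[np.ix_(ctype == t, genes)] += 5.0
            # hormone-like: drivers dominate their home type's transcriptome
            for g, t in driver_type.items():
                logits[ctype == t, g] += 8.0

            # disease trajectory: a diseased-state cell at process w interpolates
            # between its healthy origin state (w=0) and its assigned diseased
            # state (w=1), so the gradient is a real path in expression space
            origin = state.copy()
            for i, st in enumerate(diseased_states):
                origin[state == st] = healthy_states[i % len(healthy_states)]
            mix = np.zeros((n_sing, cfg.n_states))
            beta_cells = state >= 0
            idx_b = np.where(beta_cells)[0]
            w = process[idx_b]
            mix[idx_b, origin[idx_b]] += 1.0 - w
            mix[idx_b, state[idx_b]] += w

            marker_mat = np.zeros((cfg.n_states, cfg.n_genes))
            for st, genes in state_markers.items():
                marker_mat[st, genes] = 2.5
            logits += mix @ marker_mat

            act = 1.4 * (mix @ state_prog)
            act[idx_b] += rng.normal(0, 0.5, (idx_b.size, cfg.n_programs))
            for p, genes in programs.items():
                logits[:, genes] += act[:, [p]]
            logits[:, process_up] += 2.5 * process[:, None]
            logits[:, process_down] -= 2.5 * process[:, None]
            logits[:, sex_genes] += 4.0 if sex == "male" else -10.0

            p_mat = np.exp(logits - logits.max(axis=1, keepdims=True))
            p_mat /= p_mat.sum(axis=1, keepdims=True)

            # ambient profile: hormone-like drivers dominate, plus mean cell profile
            amb = np.zeros(cfg.n_genes)
            w = rng.dirichlet(np.full(cfg.n_ambient_driver_genes, 8.0))
            amb[ambient_drivers] = 0.65 * w
            amb += 0.35 * p_mat.mean(axis=0)
            amb /= amb.sum()

            lib = np.exp(rng.normal(np.log(cfg.mean_library_size), 0.25, n_sing))
            lib = np.maximum(lib, 4.0 * cfg.min_cell_counts)
            mu = lib[:, None] * ((1 - cfg.ambient_fraction) * p_mat
                                 + cfg.ambient_fraction * amb[None, :])

            pa = rng.integers(0, n_sing, n_doub) if n_doub else np.empty(0, dtype=int)
            pb = rng.integers(0, n_sing, n_doub) if n_doub else np.empty(0, dtype=int)
            if n_doub:
                mu = np.vstack([mu, mu[pa] + mu[pb]])
            n_real = mu.shape[0]

            # NB via Poisson-Gamma mixture with per-gene dispersion
            shape = 1.0 / disp
            lam = mu * rng.gamma(shape, 1.0, size=mu.shape) * disp
            counts = rng.poisson(lam).astype(np.int32)

            n_empty = cfg.n_empty_droplets
            empty_tot = rng.integers(10, cfg.min_cell_counts - 20, n_empty)
            empty_counts = (np.vstack([rng.multinomial(t, amb) for t in empty_tot])
                            if n_empty else np.empty((0, cfg.n_genes))).astype(np.int32)

            X = sp.csr_matrix(np.vstack([counts, empty_counts]))
            blocks_X.append(X)

            n_total = n_real + n_empty
            barcodes = [f"{sample}_bc{i:05d}" for i in range(n_total)]
            obs_rows.append(pd.DataFrame({
                "barcode": barcodes,
                "sample": sample,
                "dataset": f"dataset{d}",
                "condition": condition,
                "sex": sex,
            }))

            ct = np.concatenate([type_names[ctype], type_names[ctype[pa]],
                                 np.full(n_empty, "empty")])
            st_names = np.where(state >= 0, np.char.add("state", state.astype(str)), "none")
            st_lab = np.concatenate([st_names, st_names[pa], np.full(n_empty, "none")])
            pr = np.concatenate([process, process[pa], np.zeros(n_empty)])
            ct_all.append(ct)
            st_all.append(st_lab)
            proc_all.append(pr)
            doub_all.append(np.concatenate([np.zeros(n_sing, bool), np.ones(n_doub, bool),
                                            np.zeros(n_empty, bool)]))
            empty_all.append(np.concatenate([np.zeros(n_real, bool), np.ones(n_empty, bool)]))

            # latent: type one-hot-ish centers + program activities + process axis
            lat = np.zeros((n_total, 10))
            onehot = np.zeros((n_sing, cfg.n_celltypes))
            onehot[np.arange(n_sing), ctype] = 3.0
            lat[:n_sing, :min(cfg.n_celltypes, 4)] = onehot[:, :4]
            lat[:n_sing, 4:4 + min(cfg.n_programs, 5)] = act[:, :5]
            lat[:n_sing, 9] = 3.0 * process
            latent_all.append(lat)
            sample_idx += 1

    X = sp.vstack(blocks_X).tocsr()
    obs = pd.concat(obs_rows, ignore_index=True)
    obs = obs.set_index("barcode")
    obs.index.name = None

    truth = GroundTruth(
        cell_type=np.concatenate(ct_all),
        state=np.concatenate(st_all),
        disease_process=np.concatenate(proc_all),
        program_membership={gene_names[g]: f"program{p}" for p, gs in programs.items() for g in gs},
        marker_genes={f"state{s}": gene_names[gs].tolist() for s, gs in state_markers.items()},
        type_marker_genes={str(type_names[t]): gene_names[gs].tolist()
                           for t, gs in type_markers.items()},
        process_genes={"up": gene_names[process_up].tolist(),
                       "down": gene_names[process_down].tolist()},
        ambient_genes=gene_names[ambient_drivers].tolist(),
        sex_genes=gene_names[sex_genes].tolist(),
        latent=np.vstack(latent_all),
        is_doublet=np.concatenate(doub_all),
        is_empty=np.concatenate(empty_all),
    )

    obs["is_doublet"] = truth.is_doublet
    obs["is_empty"] = truth.is_empty
    obs["true_cell_type"] = truth.cell_type
    obs["true_state"] = truth.state
    obs["true_disease_process"] = truth.disease_process

    var = pd.DataFrame(index=pd.Index(gene_names, name=None))
    adata = AnnData(X=X, obs=obs, var=var)
    # the generative latent doubles as the simulated integrated embedding
    adata.obsm["X_latent"] = truth.latent
    adata.uns["synthetic_config"] = {k: (list(v) if isinstance(v, tuple) else v)
                                     for k, v in asdict(cfg).items()}
    return adata, truth


def write_synthetic(adata: AnnData, truth: GroundTruth, out_dir, overwrite: bool = False) -> None:
    """Write per-sample CellRanger-style MTX bundles, metadata.tsv and truth.json.

    On-disk matrices are genes x cells (CellRanger dialect); round-trip through
    :func:`isletkit.io.read_expression` reproduces the in-memory matrix exactly.
    """
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    os.makedirs(out_dir, exist_ok=True)

    for sample in pd.unique(adata.obs["sample"]):
        sdir = os.path.join(out_dir, sample)
        os.makedirs(sdir, exist_ok=True)
        mask = (adata.obs["sample"] == sample).to_numpy()
        Xs = sp.csc_matrix(adata.X[mask].T)  # genes x cells on disk
        mmwrite(os.path.join(sdir, "matrix.mtx"), Xs, field="integer")
        with open(os.path.join(sdir, "features.tsv"), "w") as fh:
            for g in adata.var_names:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(os.path.join(sdir, "barcodes.tsv"), "w") as fh:
            for bc in adata.obs_names[mask]:
                fh.write(bc + "\n")

    meta = adata.obs[["sample", "dataset", "condition", "sex"]].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
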
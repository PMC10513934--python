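"""Reading expression bundles (CellRanger-dialect MTX or h5ad) and gene sets (GMT)."""

from __future__ import annotations

import gzip
import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread


def _find(dirpath: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dirpath, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def _read_lines(path: str) -> list[str]:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _read_sample_dir(dirpath: str) -> AnnData:
    mtx = _find(dirpath, "matrix.mtx")
    X = mmread(mtx).T.tocsr()  # genes x cells on disk -> cells x genes
    feats = [l.split("\t")[0] for l in _read_lines(_find(dirpath, "features.tsv"))]
    barcodes = _read_lines(_find(dirpath, "barcodes.tsv"))
    if X.shape != (len(barcodes), len(feats)):
        raise ValueError(
            f"dimension mismatch in {dirpath}: matrix {X.shape[::-1]} (genes x cells) vs "
            f"{len(feats)} features, {len(barcodes)} barcodes"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes))
    var = pd.DataFrame(index=pd.Index(feats))
    return AnnData(X=X.astype(np.int32), obs=obs, var=var)


def read_expression(path) -> AnnData:
    """Load an expression dataset from an h5ad file, a single MTX sample
    directory, or a multi-sample bundle directory (sample subdirectories plus
    metadata.tsv as written by :func:`isletkit.synthetic.write_synthetic`).

    Duplicate barcodes across samples are rejected.
    """
    path = str(path)
    if path.endswith(".h5ad"):
        import anndata
        return anndata.read_h5ad(path)
    if not os.path.isdir(path):
        raise FileNotFoundError(path)
    if os.path.exists(os.path.join(path, "matrix.mtx")) or \
       os.path.exists(os.path.join(path, "matrix.mtx.gz")):
        return _read_sample_dir(path)

    subdirs = sorted(
        d for d in os.listdir(path)
        if os.path.isdir(os.path.join(path, d))
        and (os.path.exists(os.path.join(path, d, "matrix.mtx"))
             or os.path.exists(os.path.join(path, d, "matrix.mtx.gz")))
    )
    if not subdirs:
        raise FileNotFoundError(f"no MTX bundles under {path}")
    parts = []
    for d in subdirs:
        a = _read_sample_dir(os.path.join(path, d))
        a.obs["sample"] = d
        parts.append(a)
    genes = parts[0].var_names
    for a in parts[1:]:
        if not a.var_names.equals(genes):
            raise ValueError("samples have mismatched feature lists")
    X = sp.vstack([a.X for a in parts]).tocsr()
    obs = pd.concat([a.obs for a in parts])
    if obs.index.duplicated().any():
        dup = obs.index[obs.index.duplicated()][:3].tolist()
        raise ValueError(f"duplicate barcodes across samples, e.g. {dup}")
    adata = AnnData(X=X, obs=obs, var=parts[0].var.copy())

    meta_path = os.path.join(path, "metadata.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("barcode")
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise ValueError(f"metadata.tsv missing {len(missing)} barcodes")
        for col in meta.columns:
            adata.obs[col] = meta.loc[adata.obs_names, col].to_numpy()
    return adata


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in _read_lines(str(path)):
        parts = line.split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "isletkit") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), description] + [str(g) for g in genes]) + "\n")
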
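"""Shared helpers: seeded substreams, provenance headers, small numeric utilities."""

from __future__ import annotations

import hashlib
import json
from typing import Iterable

import numpy as np
import pandas as pd


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a global seed and a stage name.

    All randomness in the package flows through named substreams so that a single
    pipeline seed fully determines every stage's output regardless of execution order.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_header(stage: str, params: dict) -> str:
    """Comment header stamped on every numeric output file."""
    lines = [f"# isletkit stage={stage}"]
    for k in sorted(params):
        lines.append(f"# {k}={params[k]}")
    lines.append(f"# config_hash={config_hash(params)}")
    return "\n".join(lines) + "\n"


def parse_provenance_header(path) -> dict:
    """Read back the provenance header of an output file; raises if malformed."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
            elif body.startswith("isletkit"):
                out["stage"] = body.split("stage=", 1)[-1]
    if "config_hash" not in out:
        raise ValueError(f"missing provenance header in {path}")
    return out


def write_tsv(df: pd.DataFrame, path, stage: str, params: dict, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, params))
        df.to_csv(fh, sep="\t", index=index)


def as_dense(x) -> np.ndarray:
    """Return a dense 2-D float array from a dense or scipy-sparse matrix."""
    if hasattr(x, "toarray"):
        return np.asarray(x.toarray(), dtype=float)
    return np.asarray(x, dtype=float)


def equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins (0..n_bins-1).

    Ties are broken by original index so the assignment is deterministic.
    """
    values = np.asarray(values)
    n = len(values)
    n_bins = min(n_bins, n) if n else 1
    order = np.lexsort((np.arange(n), values))
    bins = np.empty(n, dtype=int)
    bins[order] = np.minimum((np.arange(n) * n_bins) // max(n, 1), n_bins - 1)
    return bins


def check_gene_lists_disjoint(groups: Iterable[Iterable[int]]) -> bool:
    seen: set[int] = set()
    for g in groups:
        s = set(g)
        if seen & s:
            return False
        seen |= s
    return True
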
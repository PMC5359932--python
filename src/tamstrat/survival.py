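"""Gene-signature survival-score aggregation.

Works on a user-supplied (or synthetic) table of per-gene overall-survival
z-scores from a meta-analytic source; by that source's convention a negative
z goes with a hazard ratio below 1, i.e. higher expression is favorable, and
z < -2.0 marks a significant favorable association. Signature-level scores
are arithmetic means over the genes present in the table, with an optional
permutation null over random same-size gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .diffexp import SignatureSet

FAVORABLE_Z = -2.0


@dataclass
class SetZSummary:
    set_name: str
    n_genes_scored: int
    n_missing: int
    mean_z: float
    n_favorable: int
    permutation_p: float | None = None


def validate_ztable(ztable: pd.Series) -> pd.Series:
    if not ztable.index.is_unique:
        raise ValueError("duplicate gene ids in z table")
    if not np.all(np.isfinite(ztable.to_numpy(dtype=float))):
        raise ValueError("z table contains non-finite values")
    return ztable.astype(float)


def classify_favorable(z: float, threshold: float = FAVORABLE_Z) -> bool:
    """True iff z is strictly below the favorability threshold (default -2)."""
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return bool(z < threshold)


def mean_set_zscore(
    ztable: pd.Series, signature: SignatureSet, threshold: float = FAVORABLE_Z
) -> SetZSummary:
    """Mean survival z over a signature's genes found in the table.

    Missing genes are dropped (and counted), never imputed; an empty
    intersection is an error.
    """
    ztable = validate_ztable(ztable)
    present = [g for g in signature.genes if g in ztable.index]
    if not present:
        raise ValueError(
            f"no gene of {signature.name!r} is present in the z table"
        )
    z = ztable.loc[present].to_numpy(dtype=float)
    return SetZSummary(
        set_name=signature.name,
        n_genes_scored=len(present),
        n_missing=len(signature.genes) - len(present),
        mean_z=float(z.mean()),
        n_favorable=int((z < threshold).sum()),
    )


def permutation_set_test(
    ztable: pd.Series,
    signature: SignatureSet,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Set-level permutation p for a low (favorable) mean z.

    The null draws random gene sets of the same size uniformly from the
    scored universe and counts those with mean z <= observed:
    ``p = (1 + b) / (1 + n)``. When the number of distinct same-size subsets
    is at most ``n_perm`` the null is enumerated exhaustively instead of
    sampled.
    """
    ztable = validate_ztable(ztable)
    present = [g for g in signature.genes if g in ztable.index]
    if not present:
        raise ValueError(f"no gene of {signature.name!r} is present in the z table")
    k, total = len(present), len(ztable)
    if k >= total:
        warnings.warn(
            f"signature {signature.name!r} covers the whole scored universe; p = 1",
            stacklevel=2,
        )
        return 1.0
    z = ztable.to_numpy(dtype=float)
    observed = float(ztable.loc[present].mean())
    n_subsets = comb(total, k)
    if n_subsets <= n_perm:
        means = np.fromiter(
            (z[list(idx)].mean() for idx in combinations(range(total), k)),
            dtype=float,
            count=n_subsets,
        )
        b = int((means <= observed + 1e-12).sum())
        return (1 + b) / (1 + n_subsets)
    rng = np.random.default_rng(seed)
    hits = 0
    block = 2000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        picks = np.argsort(rng.random((m, total)), axis=1)[:, :k]
        hits += int((z[picks].mean(axis=1) <= observed + 1e-12).sum())
        done += m
    return (1 + hits) / (1 + n_perm)


def summarize_signatures(
    ztable: pd.Series,
    signatures: list[SignatureSet],
    n_perm: int = 10000,
    seed: int = 0,
    threshold: float = FAVORABLE_Z,
) -> pd.DataFrame:
    """Mean z, favorable counts and permutation p for a list of signatures."""
    rows = []
    for sig in signatures:
        s = mean_set_zscore(ztable, sig, threshold=threshold)
        s.permutation_p = permutation_set_test(ztable, sig, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "set_name": s.set_name,
                "n_genes_scored": s.n_genes_scored,
                "n_missing": s.n_missing,
                "mean_z": s.mean_z,
                "n_favorable": s.n_favorable,
                "permutation_p": s.permutation_p,
            }
        )
    return pd.DataFrame(rows).set_index("set_name")
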
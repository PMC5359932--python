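"""Expression-matrix container, TPM computation, filtering and normalization.

The pipeline's substrate is a gene x sample matrix of non-negative values
tagged with a unit: raw ``counts``, length-normalized ``tpm`` (each sample
column sums to one million), or genewise z-scored ``normalized`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TPM_TOTAL = 1e6

#: Valid values for :attr:`ExpressionMatrix.unit`.
UNITS = ("counts", "tpm", "normalized")

BIOTYPES = ("protein_coding", "lncRNA", "other")
MARKER_ROLES = ("tumor_exclusive", "subgroupA_marker", "subgroupB_marker", "none")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a unit tag.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and sample ids as columns.
    unit
        One of ``counts``, ``tpm`` or ``normalized``.
    meta
        Free-form provenance (flagged genes, clipped counts, ...).
    """

    data: pd.DataFrame
    unit: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not self.data.columns.is_unique:
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy()
        if self.unit in ("counts", "tpm") and np.any(vals < 0):
            raise ValueError(f"negative values in {self.unit} matrix")
        if self.unit == "tpm" and not self.meta.get("gene_subset", False):
            # a gene-subset TPM matrix keeps its values but loses the 1e6 sum
            sums = vals.sum(axis=0)
            if np.any(sums == 0):
                bad = self.data.columns[sums == 0].tolist()
                raise ValueError(f"all-zero TPM columns: {bad}")
            if np.any(np.abs(sums - TPM_TOTAL) > 1e-6 * TPM_TOTAL):
                bad = self.data.columns[np.abs(sums - TPM_TOTAL) > 1e-6 * TPM_TOTAL]
                raise ValueError(f"TPM columns do not sum to 1e6: {list(bad)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        meta = dict(self.meta)
        if self.unit == "tpm" and len(genes) < self.shape[0]:
            meta["gene_subset"] = True
        return ExpressionMatrix(self.data.loc[genes], self.unit, meta)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[samples], self.unit, dict(self.meta))

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column ``gene_id``, header row of sample ids."""
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, unit: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, unit)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: symbol, merged-exon length, biotype, marker role.

    Backed by a DataFrame indexed by gene id with columns ``symbol``,
    ``length_bp``, ``biotype``, ``marker_role`` and ``module_id`` (0 = not a
    planted module member; only meaningful for synthetic annotations).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"symbol", "length_bp", "biotype", "marker_role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if "module_id" not in self.table.columns:
            self.table = self.table.assign(module_id=0)
        if not self.table.index.is_unique:
            raise ValueError("duplicate gene ids in annotation")
        if (self.table["length_bp"] <= 0).any():
            bad = self.table.index[self.table["length_bp"] <= 0].tolist()
            raise ValueError(f"non-positive merged-exon lengths: {bad[:5]}")
        bad_roles = set(self.table["marker_role"]) - set(MARKER_ROLES)
        if bad_roles:
            raise ValueError(f"unknown marker roles: {sorted(bad_roles)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def lengths(self, genes: Iterable[str]) -> pd.Series:
        genes = list(genes)
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise KeyError(f"no merged-exon length for gene(s): {missing[:5]}")
        return self.table.loc[genes, "length_bp"]

    def genes_with_role(self, role: str) -> list[str]:
        if role not in MARKER_ROLES:
            raise ValueError(f"unknown marker role {role!r}")
        return list(self.table.index[self.table["marker_role"] == role])

    def symbol_to_gene(self, symbol: str) -> str:
        hits = self.table.index[self.table["symbol"] == symbol].tolist()
        if not hits:
            raise KeyError(f"symbol {symbol!r} not in annotation")
        return hits[0]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def tpm_from_counts(counts: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Compute TPM from raw counts and merged-exon lengths.

    Per sample, ``rate_g = count_g / length_g`` and
    ``TPM_g = rate_g / sum(rate) * 1e6``, so every column sums to one million.

    Raises
    ------
    ValueError
        If a sample has all-zero counts (named in the message).
    KeyError
        If a gene has no length in the annotation (named in the message).
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    lengths = annotation.lengths(counts.gene_ids).to_numpy(dtype=float)
    vals = counts.data.to_numpy(dtype=float)
    zero_cols = vals.sum(axis=0) == 0
    if zero_cols.any():
        bad = counts.data.columns[zero_cols].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    rate = vals / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * TPM_TOTAL
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns), "tpm"
    )


def filter_expressed(
    tpm: ExpressionMatrix, threshold: float = 3.0, min_samples: int = 1
) -> list[str]:
    """Genes considered expressed: TPM >= threshold in at least ``min_samples``.

    The default (threshold 3, one sample) is the study's expressed-gene rule.
    Gene order is preserved.
    """
    if tpm.unit != "tpm":
        raise ValueError(f"expected a TPM matrix, got unit={tpm.unit!r}")
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    vals = tpm.data.to_numpy()
    # expressed = nonzero and at/above threshold (so threshold 0 keeps any
    # gene with a nonzero value, not all-zero rows)
    hits = ((vals >= threshold) & (vals > 0)).sum(axis=1) >= min_samples
    return list(tpm.data.index[hits])


def log_tpm(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount), for correlation/clustering on the log scale."""
    if matrix.unit != "tpm":
        raise ValueError(f"expected a TPM matrix, got unit={matrix.unit!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(
        np.log2(matrix.data + pseudocount), "normalized", dict(matrix.meta)
    )


def genewise_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row to mean 0, population SD 1.

    Rows with zero variance are set to all-zeros and listed under
    ``meta["constant_genes"]``. Requires at least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("genewise normalization requires >= 2 samples")
    vals = matrix.data.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    normed = (vals - mean) / safe_sd
    normed[constant, :] = 0.0
    out = pd.DataFrame(normed, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(
        out, "normalized", {"constant_genes": list(matrix.data.index[constant])}
    )
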
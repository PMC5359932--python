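"""Tumor-contamination QC and correction for mixed TAM expression profiles.

Three defenses against non-macrophage signal, mirroring the study design:

1. Samples with TPM > 50 for an epithelial marker (EPCAM, MSLN) are excluded
   outright (:func:`flag_contaminated_samples`).
2. Genes expressed >100-fold higher in tumor cells or T cells than in TAMs
   are blacklisted (:func:`blacklist_crosscell_genes`).
3. Remaining low-level tumor admixture is modeled as a linear mixture
   ``mixed = (1 - f) * pure_TAM + f * tumor`` and removed: ``f`` is estimated
   by least squares on tumor-exclusive marker genes (whose pure-TAM
   expression is ~0), then the tumor reference is subtracted and the profile
   rescaled (:func:`estimate_contamination`, :func:`correct_contamination`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import TPM_TOTAL, ExpressionMatrix

MAX_FRACTION = 0.95


@dataclass
class ContaminationEstimate:
    """Estimated tumor fraction for one sample."""

    sample_id: str
    fraction: float
    marker_genes_used: list[str]
    residual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= MAX_FRACTION:
            raise ValueError(f"fraction {self.fraction} outside [0, {MAX_FRACTION}]")
        if not self.marker_genes_used:
            raise ValueError("marker_genes_used must be non-empty")


def flag_contaminated_samples(
    tpm: ExpressionMatrix,
    markers: list[str],
    threshold: float = 50.0,
) -> list[str]:
    """Samples whose expression of any marker strictly exceeds ``threshold``.

    This is the study's exclusion rule: TAM samples with TPM > 50 for EPCAM
    or MSLN are presumed tumor-contaminated beyond repair. ``markers`` are
    gene ids present in the matrix; order of the returned list follows the
    matrix column order.
    """
    missing = [m for m in markers if m not in tpm.data.index]
    if missing:
        raise KeyError(f"marker gene(s) absent from matrix: {missing}")
    sub = tpm.data.loc[markers]
    bad = (sub > threshold).any(axis=0)
    return list(sub.columns[bad])


def blacklist_crosscell_genes(
    tam_tpm: ExpressionMatrix,
    tumor_tpm: ExpressionMatrix,
    tat_tpm: ExpressionMatrix,
    fold: float = 100.0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Genes >``fold``-fold higher (median TPM) in tumor or T cells than TAMs.

    Ratios use a pseudocount to avoid division by zero:
    ``(median_other + pc) / (median_tam + pc) > fold`` blacklists the gene.
    """
    for name, m in (("tam", tam_tpm), ("tumor", tumor_tpm), ("tat", tat_tpm)):
        if m.shape[1] == 0:
            raise ValueError(f"empty sample group: {name}")
    genes = tam_tpm.data.index
    if not (genes.equals(tumor_tpm.data.index) and genes.equals(tat_tpm.data.index)):
        raise ValueError("matrices must share an identical gene universe")
    med_tam = tam_tpm.data.median(axis=1).to_numpy() + pseudocount
    med_tum = tumor_tpm.data.median(axis=1).to_numpy() + pseudocount
    med_tat = tat_tpm.data.median(axis=1).to_numpy() + pseudocount
    bad = (med_tum / med_tam > fold) | (med_tat / med_tam > fold)
    return list(genes[bad])


def estimate_contamination(
    mixed_sample: pd.Series,
    tumor_reference: pd.Series,
    markers: list[str],
) -> ContaminationEstimate:
    """Least-squares tumor fraction from tumor-exclusive marker genes.

    For markers with pure-TAM expression ~0, the mixture model reduces to
    ``mixed_g = f * tumor_g``; the closed-form least-squares solution is
    ``f = sum(mixed_g * tumor_g) / sum(tumor_g^2)``, clipped to
    [0, 0.95]. A fraction at the cap indicates the sample should have been
    excluded by :func:`flag_contaminated_samples` instead.
    """
    usable = [
        m for m in markers if m in mixed_sample.index and tumor_reference.get(m, 0) > 0
    ]
    if not usable:
        raise ValueError("no usable tumor-exclusive markers (tumor TPM must be > 0)")
    m = mixed_sample.loc[usable].to_numpy(dtype=float)
    t = tumor_reference.loc[usable].to_numpy(dtype=float)
    f = float(np.clip((m * t).sum() / (t * t).sum(), 0.0, MAX_FRACTION))
    residual = float(((m - f * t) ** 2).sum())
    if f >= MAX_FRACTION:
        warnings.warn(
            f"sample {mixed_sample.name!r}: estimated tumor fraction clipped at "
            f"{MAX_FRACTION}; residual {residual:.3g} — exclude this sample instead",
            stacklevel=2,
        )
    return ContaminationEstimate(
        sample_id=str(mixed_sample.name), fraction=f, marker_genes_used=usable,
        residual=residual,
    )


def correct_contamination(
    mixed_sample: pd.Series,
    tumor_reference: pd.Series,
    estimate: ContaminationEstimate,
) -> tuple[pd.Series, int]:
    """Subtract the tumor component and rescale to a pure-TAM TPM profile.

    ``corrected_g = max(0, mixed_g - f * tumor_g) / (1 - f)``, renormalized
    to sum to 1e6. Returns the corrected profile and the number of genes
    clipped at zero.
    """
    f = estimate.fraction
    if f >= 1.0:
        raise ValueError(f"cannot correct a fraction >= 1 (got {f})")
    corrected = (mixed_sample - f * tumor_reference).clip(lower=0.0) / (1.0 - f)
    n_clipped = int(((mixed_sample - f * tumor_reference) < 0).sum())
    total = corrected.sum()
    if total == 0:
        raise ValueError(f"sample {mixed_sample.name!r}: correction removed all signal")
    return corrected / total * TPM_TOTAL, n_clipped


def correct_matrix(
    tpm: ExpressionMatrix,
    tumor_reference: pd.Series,
    markers: list[str],
) -> tuple[ExpressionMatrix, list[ContaminationEstimate]]:
    """Estimate and correct tumor contamination for every sample of a matrix."""
    if tpm.unit != "tpm":
        raise ValueError(f"expected a TPM matrix, got unit={tpm.unit!r}")
    estimates = []
    cols = {}
    for s in tpm.sample_ids:
        est = estimate_contamination(tpm.data[s], tumor_reference, markers)
        cols[s], _ = correct_contamination(tpm.data[s], tumor_reference, est)
        estimates.append(est)
    out = ExpressionMatrix(pd.DataFrame(cols, index=tpm.data.index), "tpm")
    return out, estimates
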
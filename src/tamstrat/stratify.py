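"""Subgroup stratification of TAM transcriptomes and group statistics.

PCA alone does not cleanly partition ascites TAM cohorts, so the operative
classifier is the marker-median rule: samples with CD163 TPM strictly above
the cohort median form subgroup A (alternatively activated, clinically
unfavorable), the rest subgroup B. PCA coordinates are retained as
diagnostics, and Pearson sample-correlation structure confirms the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .expression import ExpressionMatrix


@dataclass
class SubgroupAssignment:
    sample_id: str
    label: str  # "A" or "B"
    pc1: float
    pc2: float
    marker_tpm: float


def pca_project(
    normalized: ExpressionMatrix, n_components: int = 2, whiten: bool = True
) -> pd.DataFrame:
    """Sample coordinates on the top principal components.

    Samples are observations, genes features (gene-wise centering). Component
    signs are fixed by making the largest-magnitude gene loading positive, so
    projections are reproducible across runs.
    """
    n_samples = normalized.shape[1]
    if n_samples < n_components:
        raise ValueError(
            f"{n_samples} samples < {n_components} requested components"
        )
    if n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = normalized.data.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, whiten=whiten, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    return pd.DataFrame(
        coords,
        index=normalized.data.columns,
        columns=[f"pc{j + 1}" for j in range(n_components)],
    )


def assign_subgroups(
    tpm: ExpressionMatrix,
    marker: str,
    coords: pd.DataFrame | None = None,
    margin: float = 0.0,
) -> list[SubgroupAssignment]:
    """Label samples A/B by the marker-median rule (A iff TPM > median).

    Samples exactly at the median go to B (the rule requires strictly greater
    expression for A). An optional ``margin`` voids labels within +/- margin
    of the median (label "unassigned"), reflecting samples that fit neither
    subgroup.
    """
    if marker not in tpm.data.index:
        raise KeyError(f"marker gene {marker!r} absent from matrix")
    vals = tpm.data.loc[marker]
    med = float(vals.median())
    out = []
    for s in tpm.sample_ids:
        v = float(vals[s])
        if margin > 0 and abs(v - med) <= margin:
            label = "unassigned"
        else:
            label = "A" if v > med else "B"
        pc1 = float(coords.loc[s, "pc1"]) if coords is not None else float("nan")
        pc2 = float(coords.loc[s, "pc2"]) if coords is not None else float("nan")
        out.append(SubgroupAssignment(s, label, pc1, pc2, v))
    return out


def sample_correlation(
    matrix: ExpressionMatrix, order: list[str] | None = None
) -> pd.DataFrame:
    """Sample x sample Pearson correlation matrix, optionally reordered.

    Used for the subgroup-sorted correlation heatmap. Constant sample columns
    make Pearson r undefined and raise, naming the sample.
    """
    if matrix.shape[1] < 2:
        raise ValueError("sample correlation requires >= 2 samples")
    df = matrix.data if order is None else matrix.data[order]
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = df.columns[sd == 0].tolist()
        raise ValueError(f"constant sample column(s), correlation undefined: {bad}")
    corr = np.corrcoef(vals.T)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def compare_groups(
    values_a, values_b, paired: bool = False, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided t test between two groups (Student by default, Welch by flag).

    Returns (t statistic, p value); see :func:`significance_stars` for the
    conventional star mapping.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Conventional star coding: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


def bootstrap_ci(
    values, level: float = 95.0, n_boot: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the median."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("bootstrap requires at least 2 values")
    if not 0 < level < 100:
        raise ValueError(f"confidence level must lie in (0, 100), got {level}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    medians = np.median(vals[idx], axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(medians, [alpha, 100.0 - alpha])
    return float(lo), float(hi)
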
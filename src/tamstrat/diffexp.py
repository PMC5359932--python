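"""Count-based differential expression between TAM subgroups.

A small-sample negative-binomial two-group test in the exact-test tradition:
per-gene dispersions are estimated by method of moments and shrunk toward a
trimmed-mean common dispersion, counts are scaled to a common library size,
and the group sums are compared through the conditional distribution of one
group's sum given the total. For NB counts with equal per-sample dispersion
``phi`` and a shared mean under the null, that conditional distribution is a
negative hypergeometric that depends only on the group NB sizes
``s_j = n_j / phi`` — the nuisance mean cancels::

    P(Y1 = k | Y1 + Y2 = t)  ~  C(k + s1 - 1, k) * C(t - k + s2 - 1, t - k)

Two-sided p values sum the probabilities of all outcomes no more likely than
the observed one. Benjamini-Hochberg controls the FDR, and significant genes
are partitioned into signatures A and B by fold-change sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .expression import ExpressionMatrix

_MIN_PHI = 1e-8  # dispersion floor; below this the test is effectively binomial


@dataclass
class SignatureSet:
    """Named gene set with a regulation direction."""

    name: str
    genes: tuple[str, ...]
    direction: str  # "up_in_A" | "up_in_B" | "none"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")


@dataclass
class DispersionEstimates:
    common: float
    tagwise: pd.Series  # per-gene, shrunken
    raw: pd.Series  # per-gene method-of-moments (floored at 0)
    shrink_weight: float


def _split_groups(sample_ids: list[str], groups: dict[str, str]) -> tuple[list[str], list[str]]:
    labels = sorted({groups[s] for s in sample_ids})
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    ga = [s for s in sample_ids if groups[s] == labels[0]]
    gb = [s for s in sample_ids if groups[s] == labels[1]]
    return ga, gb


def estimate_dispersions(
    counts: ExpressionMatrix,
    groups: dict[str, str],
    prior_n: float = 20.0,
    shrink_weight: float | None = None,
    trim: float = 0.25,
) -> DispersionEstimates:
    """Method-of-moments NB dispersions with shrinkage toward a common value.

    Counts are scaled to the geometric-mean library size; for each gene the
    pooled within-group variance ``v`` and grand mean ``m`` give the raw
    moment estimate ``phi = (v - m) / m^2``. The common dispersion is the
    trimmed mean of the raw estimates (floored at 0); tagwise dispersions are
    ``w * common + (1 - w) * max(phi, 0)`` with
    ``w = prior_n / (prior_n + residual_df)`` unless given explicitly.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    ga, gb = _split_groups(counts.sample_ids, groups)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 samples for dispersion estimation")
    df = counts.data[ga + gb].to_numpy(dtype=float)
    lib = df.sum(axis=0)
    ref = np.exp(np.mean(np.log(lib)))
    scaled = df * (ref / lib)

    na, nb = len(ga), len(gb)
    a, b = scaled[:, :na], scaled[:, na:]
    resid_df = na + nb - 2
    pooled_var = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / resid_df
    mean = scaled.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_signed = np.where(mean > 0, (pooled_var - mean) / mean**2, 0.0)
    expressed = mean > 0
    if not expressed.any():
        raise ValueError("no gene with nonzero counts")
    common = float(max(stats_trimmed_mean(raw_signed[expressed], trim), 0.0))
    raw = np.maximum(raw_signed, 0.0)
    w = shrink_weight if shrink_weight is not None else prior_n / (prior_n + resid_df)
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"shrink weight must lie in [0, 1], got {w}")
    tagwise = w * common + (1.0 - w) * raw
    idx = counts.data.index
    return DispersionEstimates(
        common=common,
        tagwise=pd.Series(tagwise, index=idx),
        raw=pd.Series(raw, index=idx),
        shrink_weight=float(w),
    )


def stats_trimmed_mean(x: np.ndarray, trim: float) -> float:
    """Symmetric trimmed mean (fraction ``trim`` cut from each tail)."""
    x = np.sort(np.asarray(x, dtype=float))
    k = int(len(x) * trim)
    kept = x[k: len(x) - k] if len(x) > 2 * k else x
    return float(kept.mean())


def _raw_log_weights(k: np.ndarray, t: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Unnormalized conditional log-weights of y1 = k given total t.

    Negative hypergeometric for phi > 0 (NB sizes s_j = n_j / phi); exact
    binomial in the Poisson limit phi ~ 0, where huge NB sizes would lose
    floating-point precision in gammaln differences.
    """
    if phi <= _MIN_PHI * 10:
        q = n1 / (n1 + n2)
        return (
            gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
            + k * np.log(q) + (t - k) * np.log1p(-q)
        )
    s1, s2 = n1 / phi, n2 / phi
    return (
        gammaln(k + s1) - gammaln(k + 1)
        + gammaln(t - k + s2) - gammaln(t - k + 1)
    )


def _conditional_log_weights(
    t: int, n1: int, n2: int, phi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized conditional log-pmf over the relevant support.

    Enumerates the full support for moderate totals; for large ``t`` only a
    window around the conditional mode, widened until the edge mass is
    negligible relative to the peak.
    """
    if t <= 20000:
        k = np.arange(t + 1)
        lw = _raw_log_weights(k, t, n1, n2, phi)
        return k, lw - logsumexp(lw)
    center = int(round(t * n1 / (n1 + n2)))
    spread = t * np.sqrt(max(phi, _MIN_PHI) * (1.0 / n1 + 1.0 / n2) + 4.0 / t)
    half = max(2000, int(8 * spread))
    lo, hi = max(0, center - half), min(t, center + half)
    while True:
        k = np.arange(lo, hi + 1)
        lw = _raw_log_weights(k, t, n1, n2, phi)
        peak = lw.max()
        if (lo == 0 or lw[0] < peak - 45) and (hi == t or lw[-1] < peak - 45):
            break
        lo, hi = max(0, lo - half), min(t, hi + half)
    return k, lw - logsumexp(lw)


def _exact_p(y1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional p: total mass of outcomes <= observed in prob."""
    if t == 0:
        return 1.0
    k, lw = _conditional_log_weights(t, n1, n2, phi)
    pos = int(np.searchsorted(k, y1))
    if pos >= len(k) or k[pos] != y1:
        # observed value outside the enumerated window: everything beyond the
        # window is even less likely, so only window mass below obs counts
        obs_lw = -np.inf
    else:
        obs_lw = lw[pos]
    mask = lw <= obs_lw + 1e-10
    if not mask.any():
        return float(min(1.0, np.exp(obs_lw))) if np.isfinite(obs_lw) else 1e-300
    return float(min(1.0, np.exp(logsumexp(lw[mask]))))


def nb_test(
    counts: ExpressionMatrix,
    groups: dict[str, str],
    dispersions: DispersionEstimates,
) -> pd.Series:
    """Per-gene two-sided conditional NB p values for a two-group comparison.

    Counts are scaled to the geometric-mean library size and rounded; the
    first (alphabetically first-labeled) group's sum is tested against the
    conditional distribution given the total. Genes with zero total count get
    p = 1 and are listed in the returned series' ``attrs["zero_total"]``.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    ga, gb = _split_groups(counts.sample_ids, groups)
    df = counts.data[ga + gb].to_numpy(dtype=float)
    lib = df.sum(axis=0)
    ref = np.exp(np.mean(np.log(lib)))
    scaled = np.rint(df * (ref / lib)).astype(np.int64)
    na, nb = len(ga), len(gb)
    y1 = scaled[:, :na].sum(axis=1)
    tot = y1 + scaled[:, na:].sum(axis=1)
    phi = np.maximum(dispersions.tagwise.loc[counts.data.index].to_numpy(), _MIN_PHI)

    p = np.ones(len(tot))
    for i in range(len(tot)):
        if tot[i] > 0:
            p[i] = _exact_p(int(y1[i]), int(tot[i]), na, nb, phi[i])
    out = pd.Series(p, index=counts.data.index, name="p_value")
    out.attrs["zero_total"] = list(counts.data.index[tot == 0])
    return out


def adjust_fdr(p_values) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q values, in the input order.

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the sorted p values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="fdr")
    return q


def log2_fc_median_tpm(
    tpm: ExpressionMatrix, groups: dict[str, str], pseudocount: float = 1.0
) -> pd.Series:
    """log2 ratio of subgroup median TPMs (A over B), with a pseudocount."""
    ga, gb = _split_groups(tpm.sample_ids, groups)
    med_a = tpm.data[ga].median(axis=1) + pseudocount
    med_b = tpm.data[gb].median(axis=1) + pseudocount
    return np.log2(med_a / med_b).rename("log2_fc_median_tpm")


def de_table(
    counts: ExpressionMatrix,
    tpm: ExpressionMatrix,
    groups: dict[str, str],
    fdr_threshold: float = 0.05,
    dispersions: DispersionEstimates | None = None,
) -> pd.DataFrame:
    """Full DE result table: fold change, p, BH fdr and direction per gene."""
    if dispersions is None:
        dispersions = estimate_dispersions(counts, groups)
    p = nb_test(counts, groups, dispersions)
    fdr = adjust_fdr(p)
    lfc = log2_fc_median_tpm(tpm, groups)
    direction = np.where(
        fdr < fdr_threshold, np.where(lfc > 0, "up_in_A", "up_in_B"), "ns"
    )
    return pd.DataFrame(
        {
            "log2_fc_median_tpm": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        }
    )


def define_signatures(
    results: pd.DataFrame, fdr_threshold: float = 0.05
) -> tuple[SignatureSet, SignatureSet]:
    """Partition FDR-significant genes into signatures A and B by FC sign."""
    if results.empty:
        raise ValueError("empty DE results")
    sig = results[results["fdr"] < fdr_threshold]
    bad = sig[sig["log2_fc_median_tpm"] == 0]
    if not bad.empty:
        raise ValueError(
            f"significant gene(s) with zero fold change: {list(bad.index)[:5]}"
        )
    up_a = tuple(sig.index[sig["log2_fc_median_tpm"] > 0])
    up_b = tuple(sig.index[sig["log2_fc_median_tpm"] < 0])
    if not up_a and not up_b:
        warnings.warn("no significant genes: both signatures are empty", stacklevel=2)
    return (
        SignatureSet("signature_A", up_a, "up_in_A"),
        SignatureSet("signature_B", up_b, "up_in_B"),
    )
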
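"""Synthetic mixed TAM / tumor / T-cell transcriptome cohorts with ground truth.

The generator emulates an ovarian-cancer ascites cohort: two TAM subgroups
(A: CD163/IL6/PCOLCE2-high, ECM-like; B: interferon-stimulated-gene-high),
per-sample tumor-cell contamination, tumor-exclusive epithelial markers
(EPCAM, MSLN and companions), planted coexpression modules driven by shared
latent factors, and negative-binomial count noise. Every planted feature is
recorded exactly in a :class:`SyntheticTruth` so downstream stages can be
scored against it.

Construction of a TAM sample, on the natural-log TPM scale::

    ln mu_gs = ln base_g  +/- (ln2 * de_log2_effect / 2)   # signature blocks
             + lambda_g * F_{m(g), s}                       # module factor

where ``F`` is a per-sample standard-normal factor shared by all genes of a
module and ``lambda_g`` is calibrated so that the realized pairwise log-TPM
correlation (including NB count noise) is approximately ``module_correlation``.
The expected TPM profile is renormalized to 1e6, mixed with the tumor
reference as ``(1-f) * tam + f * tumor``, converted to expected counts via
gene length and library size, and counts are drawn NB(mean, dispersion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import TPM_TOTAL, ExpressionMatrix, GeneAnnotation


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# Default contamination fractions, cycled over TAM samples. The emulated
# cohort was pre-screened for very low tumor admixture (epithelial-marker
# TPM < 50); with tumor-cell EPCAM at a few thousand TPM that screen implies
# residual fractions below ~1.5%.
_DEFAULT_FRACTIONS = (0.0, 0.003, 0.006, 0.009, 0.012, 0.015)

_SUBGROUP_A_SYMBOLS = ("CD163", "IL6", "PCOLCE2")
_TUMOR_SYMBOLS = ("EPCAM", "MSLN")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions at desk scale: a 6 + 6 TAM cohort,
    tumor and T-cell reference samples, contamination fractions below the
    exclusion threshold, a 4-fold planted subgroup effect, and three planted
    modules of which the first two coincide with signatures A and B.
    """

    n_genes: int = 2000
    n_tam_per_subgroup: int = 6
    n_tam_intermediate: int = 0
    n_tumor_samples: int = 5
    n_tat_samples: int = 5
    contamination_fractions: Sequence[float] | None = None
    de_log2_effect: float = 2.0
    module_sizes: Sequence[int] = (25, 40, 20)
    module_correlation: float = 0.9
    nb_dispersion: float = 0.05
    library_size_mean: int = 3_000_000
    n_tumor_markers: int = 12
    tpm_log_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tam_per_subgroup <= 0:
            raise ConfigurationError("n_genes and n_tam_per_subgroup must be positive")
        if min(self.n_tumor_samples, self.n_tat_samples, self.n_tam_intermediate) < 0:
            raise ConfigurationError("sample counts must be non-negative")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if sum(self.module_sizes) + self.n_tumor_markers > self.n_genes:
            raise ConfigurationError(
                f"module sizes ({sum(self.module_sizes)}) plus tumor markers "
                f"({self.n_tumor_markers}) exceed n_genes ({self.n_genes})"
            )
        if not 0 < self.module_correlation < 1:
            raise ConfigurationError("module_correlation must lie in (0, 1)")
        if self.nb_dispersion <= 0 or self.de_log2_effect <= 0:
            raise ConfigurationError("nb_dispersion and de_log2_effect must be positive")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be positive")
        if self.n_tumor_markers < 2:
            raise ConfigurationError("need at least 2 tumor-exclusive markers")
        fr = self.tam_fractions()
        if any(f < 0 or f > 0.95 for f in fr):
            raise ConfigurationError("contamination fractions must lie in [0, 0.95]")

    def tam_fractions(self) -> list[float]:
        """Per-TAM-sample contamination fractions (cycled default if unset)."""
        n = 2 * self.n_tam_per_subgroup + self.n_tam_intermediate
        if self.contamination_fractions is None:
            return [_DEFAULT_FRACTIONS[i % len(_DEFAULT_FRACTIONS)] for i in range(n)]
        fr = list(self.contamination_fractions)
        if len(fr) == 1:
            fr = fr * n
        if len(fr) != n:
            raise ConfigurationError(
                f"need {n} contamination fractions, got {len(fr)}"
            )
        return fr


@dataclass
class SyntheticTruth:
    """Exact planted ground truth for one synthetic cohort."""

    true_subgroup: dict[str, str]
    true_contamination: dict[str, float]
    true_de_genes: dict[str, str]  # gene -> "up_in_A" | "up_in_B"
    true_modules: dict[str, int]  # gene -> 1-based module id
    pure_profiles: pd.DataFrame  # gene x TAM-sample expected TPM before mixing

    def module_genes(self, module_id: int) -> list[str]:
        return [g for g, m in self.true_modules.items() if m == module_id]


@dataclass
class References:
    """Pure-population mean TPM profiles and the matching annotation."""

    annotation: GeneAnnotation
    profiles: pd.DataFrame  # gene x {tam_baseline, tumor, tcell}, columns sum to 1e6


def _gene_symbols(config: SimulationConfig) -> tuple[list[str], list[str], list[int]]:
    """Symbols, marker roles and module ids for every gene, in index order."""
    n = config.n_genes
    symbols = [f"BG{i:05d}" for i in range(n)]
    roles = ["none"] * n
    modules = [0] * n

    pos = 0
    # Tumor-exclusive epithelial-like markers first.
    for j in range(config.n_tumor_markers):
        symbols[pos] = _TUMOR_SYMBOLS[j] if j < 2 else f"TEX{j - 1:02d}"
        roles[pos] = "tumor_exclusive"
        pos += 1
    # Planted modules; module 1 = signature A block, module 2 = signature B.
    for m, size in enumerate(config.module_sizes, start=1):
        for j in range(size):
            if m == 1:
                symbols[pos] = (
                    _SUBGROUP_A_SYMBOLS[j] if j < 3 else f"ECMA{j - 2:03d}"
                )
                roles[pos] = "subgroupA_marker"
            elif m == 2:
                symbols[pos] = f"ISG{j + 1:03d}"
                roles[pos] = "subgroupB_marker"
            else:
                symbols[pos] = f"MOD{m}_{j + 1:03d}"
            modules[pos] = m
            pos += 1
    return symbols, roles, modules


def generate_references(config: SimulationConfig) -> References:
    """Build gene annotation and pure-population reference TPM profiles.

    Tumor-exclusive markers have expected TPM exactly 0 in the TAM baseline
    and T-cell profiles and at least 500 in the tumor profile. Every profile
    column is renormalized to sum to 1e6.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    symbols, roles, modules = _gene_symbols(config)
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]

    lengths = np.clip(
        np.exp(rng.normal(math.log(1500.0), 0.7, size=n)), 200, None
    ).astype(int)
    biotype = np.where(rng.random(n) < 0.1, "lncRNA", "protein_coding")
    # Keep all flagged/marker genes protein coding.
    biotype[np.array(roles) != "none"] = "protein_coding"
    biotype[np.array(modules) > 0] = "protein_coding"

    # Lognormal baseline calibrated so a column sums to ~1e6 before the final
    # renormalization (mean TPM must be 1e6 / n_genes).
    sd = config.tpm_log_sd
    mu = math.log(TPM_TOTAL / n) - sd * sd / 2.0
    base = np.exp(rng.normal(mu, sd, size=n))
    tumor = base * np.exp(rng.normal(0.0, 0.8, size=n))
    tcell = base * np.exp(rng.normal(0.0, 0.8, size=n))

    role_arr = np.array(roles)
    tex = role_arr == "tumor_exclusive"
    base[tex] = 0.0
    tcell[tex] = 0.0
    tumor_marker_tpm = rng.uniform(600.0, 3000.0, size=tex.sum())

    # Give the named subgroup markers realistic macrophage expression levels.
    for sym, level in (("CD163", 400.0), ("IL6", 120.0), ("PCOLCE2", 80.0)):
        if sym in symbols:  # absent when the signature-A block is tiny
            base[symbols.index(sym)] = level
    # A handful of T-cell-exclusive genes (CD3-like) for the blacklist stage.
    module_arr = np.array(modules)
    tcl = rng.choice(
        np.flatnonzero((role_arr == "none") & (module_arr == 0)), size=5, replace=False
    )
    base[tcl] = 0.0
    tumor[tcl] = 0.0
    tcl_tpm = rng.uniform(500.0, 2000.0, size=5)
    for k, idx in enumerate(tcl):
        symbols[idx] = f"TCEX{k + 1:02d}"

    def _with_exclusive(col: np.ndarray, idx, exact_tpm: np.ndarray) -> np.ndarray:
        """Insert cell-type-exclusive TPMs exactly; scale the rest to fill 1e6."""
        out = col.copy()
        out[idx] = 0.0
        out *= (TPM_TOTAL - exact_tpm.sum()) / out.sum()
        out[idx] = exact_tpm
        return out

    tumor[tex] = 0.0
    tcell[tcl] = 0.0
    profiles = pd.DataFrame(
        {
            "tam_baseline": base / base.sum() * TPM_TOTAL,
            "tumor": _with_exclusive(tumor, tex, tumor_marker_tpm),
            "tcell": _with_exclusive(tcell, tcl, tcl_tpm),
        },
        index=gene_ids,
    )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": symbols,
                "length_bp": lengths,
                "biotype": biotype,
                "marker_role": roles,
                "module_id": modules,
            },
            index=gene_ids,
        )
    )
    return References(annotation, profiles)


def _expected_counts(tpm: np.ndarray, lengths: np.ndarray, library_size: float) -> np.ndarray:
    """Expected read counts for a TPM profile at a given library size."""
    w = tpm * lengths
    return library_size * w / w.sum()


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def generate_cohort(
    config: SimulationConfig, references: References
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a count cohort (TAM, tumor, T-cell samples) plus ground truth.

    TAM samples mix the subgroup-shifted pure profile with the tumor reference
    at the configured contamination fraction before count sampling; tumor and
    T-cell samples are drawn around their references with mild per-sample
    biological jitter. Identical configs give byte-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ann = references.annotation.table
    lengths = ann["length_bp"].to_numpy(dtype=float)
    gene_ids = list(ann.index)
    n = config.n_genes
    phi = config.nb_dispersion

    base = references.profiles["tam_baseline"].to_numpy(dtype=float)
    tumor_ref = references.profiles["tumor"].to_numpy(dtype=float)
    tcell_ref = references.profiles["tcell"].to_numpy(dtype=float)

    modules = ann["module_id"].to_numpy()
    shift = math.log(2.0) * config.de_log2_effect / 2.0
    # Per-gene factor loading, calibrated so log-TPM pairwise correlation
    # within a module approximates module_correlation despite NB count noise:
    # r = common_var / (common_var + sigma_eps^2). For the signature modules
    # (1 and 2) the planted subgroup shift is itself common signal across the
    # cohort, so the latent factor only tops up the remainder.
    mean_count_guess = _expected_counts(base, lengths, config.library_size_mean)
    sigma_eps = np.sqrt(phi + 1.0 / np.maximum(mean_count_guess, 1.0))
    rho = config.module_correlation
    n_tam = 2 * config.n_tam_per_subgroup + config.n_tam_intermediate
    shift_var = shift**2 * (2 * config.n_tam_per_subgroup) / n_tam
    target_var = sigma_eps**2 * rho / (1.0 - rho)
    loading = np.sqrt(target_var)
    loading_sig = np.sqrt(np.maximum(target_var - shift_var, 0.0))
    sig_a = modules == 1 if len(config.module_sizes) >= 1 else np.zeros(n, bool)
    sig_b = modules == 2 if len(config.module_sizes) >= 2 else np.zeros(n, bool)

    n_a = config.n_tam_per_subgroup
    tam_labels = ["A"] * n_a + ["B"] * n_a + ["I"] * config.n_tam_intermediate
    tam_names = (
        [f"TAM_A{i + 1:02d}" for i in range(n_a)]
        + [f"TAM_B{i + 1:02d}" for i in range(n_a)]
        + [f"TAM_I{i + 1:02d}" for i in range(config.n_tam_intermediate)]
    )
    fractions = config.tam_fractions()

    # Per-sample module factors. Distinct transcriptional programs are planted
    # as mutually orthogonal sample patterns (also orthogonal to the subgroup
    # shift), so that at small n modules do not mix by chance.
    n_mod = len(config.module_sizes)
    factors = rng.normal(size=(n_tam, n_mod)) if n_mod else np.zeros((n_tam, 0))
    if 0 < n_mod < n_tam:
        shift_pattern = np.array([1.0] * n_a + [-1.0] * n_a + [0.0] * config.n_tam_intermediate)
        q, _ = np.linalg.qr(np.column_stack([shift_pattern, factors]))
        factors = q[:, 1:] * math.sqrt(n_tam)

    counts: dict[str, np.ndarray] = {}
    pure: dict[str, np.ndarray] = {}
    positive = base > 0

    for i, (name, label, f) in enumerate(zip(tam_names, tam_labels, fractions)):
        ln = np.where(positive, np.log(np.maximum(base, 1e-300)), -np.inf)
        if label == "A":
            ln = ln + shift * sig_a - shift * sig_b
        elif label == "B":
            ln = ln - shift * sig_a + shift * sig_b
        # intermediates: no subgroup shift (50/50 behaviour)
        for m in range(1, n_mod + 1):
            lam = loading_sig if m in (1, 2) else loading
            in_m = modules == m
            ln = np.where(in_m, ln + lam * factors[i, m - 1], ln)
        tam_tpm = np.where(positive, np.exp(ln), 0.0)
        tam_tpm = tam_tpm / tam_tpm.sum() * TPM_TOTAL
        pure[name] = tam_tpm
        mixed = (1.0 - f) * tam_tpm + f * tumor_ref
        lib = config.library_size_mean * rng.uniform(0.8, 1.2)
        counts[name] = _nb_sample(rng, _expected_counts(mixed, lengths, lib), phi)

    for group, ref, count_n in (
        ("TUM", tumor_ref, config.n_tumor_samples),
        ("TAT", tcell_ref, config.n_tat_samples),
    ):
        for i in range(count_n):
            jitter = np.exp(rng.normal(0.0, 0.15, size=n))
            prof = ref * jitter
            prof = prof / prof.sum() * TPM_TOTAL
            lib = config.library_size_mean * rng.uniform(0.8, 1.2)
            counts[f"{group}{i + 1:02d}"] = _nb_sample(
                rng, _expected_counts(prof, lengths, lib), phi
            )

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids).astype(np.int64), "counts"
    )
    de_genes: dict[str, str] = {}
    for g, up in zip(np.array(gene_ids)[sig_a], ["up_in_A"] * int(sig_a.sum())):
        de_genes[g] = up
    for g in np.array(gene_ids)[sig_b]:
        de_genes[g] = "up_in_B"
    truth = SyntheticTruth(
        true_subgroup=dict(zip(tam_names, tam_labels)),
        true_contamination=dict(zip(tam_names, fractions)),
        true_de_genes=de_genes,
        true_modules={g: int(m) for g, m in zip(gene_ids, modules) if m > 0},
        pure_profiles=pd.DataFrame(pure, index=gene_ids),
    )
    return matrix, truth


def make_survival_ztable(
    references: References, seed: int = 0
) -> pd.Series:
    """Synthetic gene -> overall-survival z-score table.

    Emulates a meta-analytic survival table: background genes draw z from a
    standard normal; signature-B (interferon-like) genes are shifted strongly
    negative (favorable outcome, HR < 1) and signature-A (ECM-like) genes
    moderately positive (unfavorable), matching the direction convention in
    which negative z means longer overall survival.
    """
    ann = references.annotation.table
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    z = rng.normal(0.0, 1.0, size=len(ann))
    role = ann["marker_role"].to_numpy()
    z[role == "subgroupB_marker"] = rng.normal(-2.5, 0.8, (role == "subgroupB_marker").sum())
    z[role == "subgroupA_marker"] = rng.normal(1.5, 0.8, (role == "subgroupA_marker").sum())
    return pd.Series(z, index=ann.index, name="z")
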
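# Methods

This note documents the models, parameter choices and limitations behind
`tamstrat`. The package analyses bulk RNA-seq profiles of tumor-associated
macrophages (TAMs) from ovarian-cancer ascites and stratifies patients into
an ECM/CD163-high subgroup (A) and an interferon-signature subgroup (B).

## Expression model and preprocessing

Counts are converted to TPM using merged-exon lengths:
`rate_g = count_g / length_g`, `TPM_g = rate_g / Σ rate · 10⁶`. No
pseudocount is used; all-zero samples are a hard error. A gene is
*expressed* if its TPM reaches 3 in at least one sample (both knobs
exposed); "at least one sample" is the most permissive reading of the
threshold and is deliberate — downstream stages re-filter by variance or
significance anyway. Genewise normalization is per-gene z-scoring with the
population SD; zero-variance rows become zeros and are flagged rather than
dropped, so matrix shapes stay aligned.

## Contamination model

A mixed TAM profile is modeled as a two-component linear mixture on the TPM
scale, `mixed = (1−f)·TAM + f·tumor`, with both components summing to 10⁶.
Three defenses are applied in order:

1. **Screen** — samples with *EPCAM* or *MSLN* TPM strictly above 50 are
   excluded outright (the strictness matters: a sample at exactly 50 is
   retained).
2. **Blacklist** — genes with `(median_other + 1) / (median_TAM + 1) > 100`
   for tumor or T cells are removed from analysis. The pseudocount of 1 TPM
   avoids division by zero and is configurable.
3. **Unmixing** — for tumor-exclusive marker genes the TAM component
   vanishes, so `f = Σ m_g t_g / Σ t_g²` (closed-form least squares over the
   marker panel), clipped to [0, 0.95]. Correction is
   `max(0, mixed − f·tumor) / (1 − f)`, renormalized to 10⁶; the number of
   zero-clipped genes is reported. A fraction at the 0.95 cap signals a
   sample that should have been screened out instead, and warns.

T-cell contamination is handled only by the blacklist, not by unmixing; the
mixture model is deliberately two-component. With the default marker panel
(12 tumor-exclusive genes) and NB dispersion 0.05, recovery error is about
0.01 mean absolute at f ∈ {0.1, 0.3}; a 2-gene panel would be several times
noisier, which is why the synthetic annotation flags a panel rather than
only the two named markers.

## Subgroup assignment

PCA (2 components, whitened, gene-wise centering, deterministic sign
convention) is diagnostic only: the operative classifier is the
marker-median rule — subgroup A iff CD163 TPM strictly exceeds the cohort
median, ties to B. An optional `margin` voids labels within ±ε of the
median, reflecting cohorts in which some samples fit neither subgroup. The
group-comparison statistics are two-sided t tests (Student by default,
Welch by flag) and percentile bootstrap CIs of the median (10 000 resamples).

## Differential expression

The DE stage is written from scratch rather than wrapped from an existing
count-DE package, so that the computation itself is part of the tested
surface:

* **Library scaling** — total-count scaling to the geometric-mean library
  size (no TMM; simplest defensible choice, isolated behind one function).
* **Dispersion** — per-gene method-of-moments estimates
  `φ_g = (v_g − m_g)/m_g²` from pooled within-group variances; the common
  dispersion is their 25 %-trimmed mean; tagwise values shrink toward the
  common one with weight `w = prior_n / (prior_n + residual_df)`,
  `prior_n = 20`. At 6 + 6 samples this gives w ≈ 0.67 — heavy shrinkage,
  appropriate for the tiny replication the design targets.
* **Test** — conditional exact-style test on the scaled, rounded group
  sums. For NB counts with equal per-sample mean and dispersion φ, the
  distribution of one group's sum given the total depends only on the NB
  sizes `n_j/φ` (negative hypergeometric); the nuisance mean cancels. The
  two-sided p sums all outcomes no more likely than the observed one. As
  φ → 0 the law becomes exactly binomial, and that branch is computed in
  binomial form directly (huge NB sizes would otherwise lose precision in
  gammaln differences). For totals above 20 000 only a window around the
  conditional mode is enumerated, widened until the edge mass is below
  e⁻⁴⁵ of the peak.
* **FDR** — Benjamini–Hochberg step-up, own implementation, cross-checked
  in tests against a brute-force step-up and statsmodels.
* **Fold change** — reported as log2 of the ratio of subgroup median TPMs
  (pseudocount 1), matching how the effect is usually displayed, not a
  model-fitted coefficient. Signatures A/B are the FDR-significant genes
  split by fold-change sign.

Calibration, measured by the acceptance suite on all-null NB cohorts
(5000 genes, 6 + 6 samples, dispersion 0.1, ~120 reads/gene median): type-I
error ≈ 0.054 at nominal 0.05, within the 0.04–0.07 acceptance band;
planted 4-fold effects are recovered with recall ≥ 0.95 at empirical
FDR ≤ 0.08. Calibration simulations use an expressed-gene depth regime
because the pipeline always applies the TPM ≥ 3 filter before DE; very
low-count genes would be discarded upstream. In the full pipeline the DE
stage runs on contamination-corrected pseudo-counts (corrected TPM mapped
back to each sample's library size and rounded); this slightly violates the
NB sampling model but removes tumor-driven false positives, and the
correction is tiny at the default contamination levels.

## Coexpression procedure

Candidates are the k = 3000 genes of greatest TPM variance (ties broken by
gene id). For each candidate g, the neighborhood
`S(g) = {g′ : r(g,g′) > 0.89}` is kept when `|S(g)| > 10` (both thresholds
strict), and the union of kept neighborhoods ∪ their seeds is the combined
gene set. Gene clustering is WPGMA ("weighted") agglomeration on
correlation distance `1 − r`, cut at height 0.8; clusters are relabeled
I, II, … by descending size, ties by lexicographically smallest member.
Sample clustering applies the same linkage to sample profiles over the
combined genes and reports the two top branches. Overlap statistics are
exact intersection counts with percent-of-x to one decimal.

The detection input is a genewise-normalized matrix; because expression is
approximately lognormal, correlations are best computed on the log scale
(`expression.log_tpm` gives log2(TPM+1)) — heavy linear-scale tails
attenuate Pearson r by several hundredths, which matters against a 0.89
threshold. The pipeline exposes both; recovery guarantees in the test suite
are stated on the log scale.

## Survival aggregation

Per-gene overall-survival z-scores come from a user-supplied (or synthetic)
meta-analytic table with the convention negative z ⇔ HR < 1 ⇔ favorable;
z < −2.0 (strict) marks a significant favorable association. A signature's
score is the arithmetic mean over its genes present in the table — missing
genes are dropped and counted, never zero-imputed (imputation would bias
toward the null). The permutation null draws random same-size gene sets
uniformly from the scored universe, `p = (1 + b)/(1 + n)`; when the number
of distinct subsets is at most `n_perm`, the null is enumerated
exhaustively instead of sampled. Expression-matched null sets are a
documented extension point, not implemented.

## Synthetic cohorts

The generator emulates the study design at desk scale, and its defaults are
the package's reference conditions:

| parameter | default | rationale |
| --- | --- | --- |
| n_genes | 2000 | desk-scale transcriptome |
| TAM samples | 6 + 6 | the subgroup sizes of the emulated cohort |
| library_size_mean | 3·10⁶ | ~1500 reads/gene, matching ~20–36 M reads over ~20 k genes |
| nb_dispersion | 0.05 | purified-population biological replication |
| de_log2_effect | 2.0 | 4-fold subgroup marker separation |
| module_sizes | (25, 40, 20) | signature A, signature B, neutral module |
| module_correlation | 0.9 | within-module log-scale Pearson target |
| contamination | 0–1.5 % | residual fractions implied by the EPCAM/MSLN < 50 screen |
| tumor markers | 12 | EPCAM, MSLN + 10 epithelial-like companions |

Construction: per-gene baseline TPM is lognormal with mean 10⁶/n_genes;
tumor and T-cell references multiply the baseline by lognormal
perturbations; cell-type-exclusive genes (tumor markers at 600–3000 TPM,
five T-cell-exclusive genes) are inserted exactly after rescaling the
remainder, so reference columns sum to 10⁶ and marker levels are controlled.
For each TAM sample, signature blocks shift by ±log2-effect/2, module
latent factors add `λ_g · F_{m,s}` on the natural-log scale, the profile is
renormalized, mixed with the tumor reference at the sample's contamination
fraction, converted to expected counts via gene length and library size,
and counts drawn NB with `var = μ + φμ²`.

Two calibration details are deliberate design choices. First, the factor
loading targets the *total* common-signal fraction: for signature modules
the planted subgroup shift already supplies common variance, so the factor
only tops up the remainder (otherwise the factor noise would drown the
4-fold CD163 separation that subgroup assignment relies on). Second, module
factor vectors are drawn mutually orthogonal across samples and orthogonal
to the shift pattern (QR of a Gaussian matrix): with iid factors at n = 18,
chance factor–factor correlations (sd ≈ 0.24) would merge distinct modules
under the 0.8 dendrogram cut in a large fraction of cohorts. Orthogonal
planting encodes the intended semantics — distinct transcriptional
programs — rather than hiding a detection weakness.

What the generator does **not** emulate: gene-length/GC biases, outlier
samples, batch effects, compositional (non-mixture) contamination,
heavy-tailed per-gene dispersion, or correlated background genes. Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artifact of real cohorts.

The synthetic survival table draws background z from N(0,1), signature-B
genes from N(−2.5, 0.8) and signature-A genes from N(+1.5, 0.8), mirroring
the favorable interferon / unfavorable ECM direction structure the method
is meant to detect.

## Numerical and determinism choices

* Every stochastic component takes an explicit seed; the pipeline fans a
  single seed out to stages, and identical configs give byte-identical
  outputs (reports are JSON with sorted keys).
* PCA component signs are fixed by making the largest-magnitude loading
  positive; dendrogram cluster labels are relabeled by size then smallest
  member; gene lists are sorted — all to make re-runs diff-stable.
* The two-sided conditional test compares outcome probabilities with a
  1e-10 relative tolerance when accumulating the rejection mass; mirrored
  label swaps can therefore differ by ~1e-3 in p for borderline outcomes.
* Degenerate inputs fail loudly with the offending gene/sample named:
  all-zero samples, missing lengths, constant columns under correlation,
  empty combined sets, fractions ≥ 1.

## Problem sizes

The test and acceptance workloads are sized for a single CPU: 5000-gene
all-null calibration across 10–20 seeds, 1200–2000-gene cohorts elsewhere,
10 000 bootstrap/permutation resamples (reduced where a test only checks
determinism). These sizes are the package's own reference conditions; the
algorithms themselves stream over genes and scale linearly in the gene
count except for the O(k²) candidate correlation matrix.

## Known limitations

* The unmixing assumes the tumor reference profile is known and matches the
  contaminating cells; patient-specific tumor drift is not modeled.
* Library-size normalization is total-count only; strongly asymmetric DE
  would bias it (TMM is an extension point).
* The exact-style test conditions on rounded scaled sums; at very unequal
  library sizes the rounding is a further approximation.
* The marker-median classifier labels every retained sample; cohorts with
  genuine intermediates need the `margin` option or external curation.
* Survival aggregation treats gene z-scores as exchangeable; no
  expression-level matching in the permutation null.
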
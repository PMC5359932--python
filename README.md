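# tamstrat

Stratification of **tumor-associated macrophage (TAM) transcriptomes** from
ovarian-cancer ascites, as a tested, reusable pipeline.

Bulk RNA-seq profiles of macrophages isolated from malignant ascites mix the
macrophage signal with tumor-cell contamination, and the patients themselves
fall into biologically distinct subgroups: subgroup **A** expresses high
levels of clinically unfavorable markers (*CD163*, *IL6*, *PCOLCE2*,
extracellular-matrix programs), while subgroup **B** upregulates
interferon-stimulated immune-defense genes — a signature associated with
longer overall survival. `tamstrat` implements every analysis stage needed to
reproduce this kind of stratification, plus a synthetic-cohort generator with
exact planted ground truth so the whole method is verifiable offline:

1. **Expression** — TPM from counts and merged-exon lengths
   (`TPM_g = (c_g/l_g) / Σ(c/l) · 10⁶`), the expressed-gene filter
   (TPM ≥ 3), and genewise z-scoring.
2. **Purity** — exclusion of samples with epithelial-marker TPM > 50
   (*EPCAM*, *MSLN*); blacklisting of genes >100-fold higher in tumor or T
   cells than TAMs; linear unmixing `mixed = (1−f)·TAM + f·tumor` with `f`
   estimated in closed form from tumor-exclusive markers, followed by
   subtract-and-rescale correction.
3. **Stratify** — whitened 2-component PCA diagnostics and the operative
   classifier: subgroup A iff CD163 TPM strictly exceeds the cohort median;
   Pearson sample-correlation structure; t tests and bootstrap CIs.
4. **Diffexp** — a small-sample negative-binomial exact-style test:
   method-of-moments dispersions shrunk toward a trimmed-mean common value,
   then the conditional distribution of one group's (library-size-scaled)
   count sum given the total, which for equal dispersion is a negative
   hypergeometric free of the nuisance mean. Benjamini–Hochberg FDR; the
   significant genes split by fold-change sign into signatures A and B.
5. **Coexpress** — top-variance gene selection, correlation-neighborhood
   combination (r > 0.89, neighborhood size > 10), WPGMA (weighted-linkage)
   clustering on correlation distance `1 − r` cut at 0.8, two-branch sample
   clustering, and cluster/signature overlap percentages.
6. **Survival** — mean per-gene overall-survival z-scores over a signature
   (negative z ⇔ HR < 1 ⇔ favorable; z < −2 significant), with a
   permutation null over random same-size gene sets.
7. **Synthetic data** — NB-count cohorts with planted subgroups (4-fold
   marker effects), latent-factor coexpression modules, tumor-exclusive
   markers and per-sample contamination fractions, all recorded exactly.

## Worked example

Run the full pipeline on the default synthetic cohort (2000 genes, 6 + 6 TAM
samples, 5 tumor and 5 T-cell references):

```bash
tamstrat run --out run1 --seed 1
```

or from Python via `tamstrat.run_pipeline(PipelineConfig(seed=1))`. The
narrative scripts in `examples/` walk through each stage; for instance
`python examples/03_stratify_and_de.py` prints

```
CD163-median assignment: 12/12 samples match planted truth
signature A: 28 genes (25/25 planted recovered)
signature B: 42 genes (40/40 planted recovered)
```

meaning the marker-median rule reproduces the planted subgroups exactly and
the NB test recovers all 25 + 40 planted differentially expressed genes (the
3 + 2 extra calls are false positives controlled at FDR < 0.05). The
coexpression stage (`examples/04_coexpression.py`) then shows that the
clusters found by correlation thresholding + WPGMA align with the same
programs discovered by DE:

```
cluster_I (41 genes) ∩ signature_B: 40 = 97.6%
cluster_II (25 genes) ∩ signature_A: 24 = 96.0%
```

and the survival stage (`examples/05_survival.py`) scores the
interferon-like signature B strongly favorable:

```
             n_genes_scored  n_missing  mean_z  n_favorable  permutation_p
signature_A              28          0  1.2639            0         1.0000
signature_B              42          0 -2.4185           27         0.0001
```

## Layout

```
src/tamstrat/      library (expression, purity, stratify, diffexp,
                   coexpress, survival, synthetic_data, pipeline, cli, io)
examples/          one narrative script per capability
tests/             pytest suite incl. acceptance properties
scripts/           acceptance.py
docs/methods.md    models, parameter choices, limitations
```
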
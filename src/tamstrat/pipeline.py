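"""End-to-end orchestration: simulate -> QC -> correct -> stratify -> DE ->
coexpression -> survival, with every intermediate persisted as TSV/GMT and a
machine-readable run report.

Stage parameters default to the study's thresholds: expressed TPM >= 3,
EPCAM/MSLN exclusion at TPM > 50, >100-fold cross-cell blacklist, CD163
median subgrouping, FDR < 0.05, top-3000 variance genes, r > 0.89 / n > 10
set combination, dendrogram cut 0.8, favorable survival z < -2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpress, diffexp, io, purity, stratify, survival
from .expression import (
    ExpressionMatrix,
    GeneAnnotation,
    filter_expressed,
    genewise_normalize,
    tpm_from_counts,
)
from .synthetic_data import (
    References,
    SimulationConfig,
    generate_cohort,
    generate_references,
    make_survival_ztable,
)

log = logging.getLogger("tamstrat")


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run (study defaults)."""

    out_dir: str = "tamstrat_run"
    seed: int = 0
    expressed_tpm: float = 3.0
    expressed_min_samples: int = 1
    contamination_marker_tpm: float = 50.0
    crosscell_fold: float = 100.0
    crosscell_pseudocount: float = 1.0
    marker_symbol: str = "CD163"
    fdr: float = 0.05
    k_top_variance: int = 3000
    r_min: float = 0.89
    min_set_size: int = 10
    cut_height: float = 0.8
    favorable_z: float = -2.0
    n_perm: int = 10000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


@dataclass
class RunReport:
    """Per-stage dimensions, exclusions and summary statistics of one run."""

    seed: int
    n_genes: int
    tam_samples: list[str]
    excluded_samples: list[str]
    contamination: dict[str, float]
    n_expressed: int
    blacklist: list[str]
    subgroup: dict[str, str]
    n_signature_a: int
    n_signature_b: int
    cluster_sizes: dict[str, int]
    n_combined_genes: int
    sample_partition: dict[str, int]
    overlaps: list[dict]
    survival_summary: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _tumor_marker_ids(annotation: GeneAnnotation) -> list[str]:
    ids = annotation.genes_with_role("tumor_exclusive")
    if not ids:
        raise ValueError("annotation flags no tumor-exclusive markers")
    return ids


def run_pipeline(
    config: PipelineConfig,
    counts: ExpressionMatrix | None = None,
    references: References | None = None,
    ztable: pd.Series | None = None,
) -> RunReport:
    """Execute the full stratification pipeline and persist all intermediates.

    When ``counts``/``references``/``ztable`` are not supplied they are
    simulated from ``config.simulation`` (with the pipeline seed), so the
    default invocation is fully self-contained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = config.simulation
    if references is None:
        sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
        references = generate_references(sim)
    ann = references.annotation
    if counts is None:
        counts, truth = generate_cohort(sim, references)
        truth.pure_profiles.to_csv(out / "truth_pure_profiles.tsv", sep="\t")
        pd.Series(truth.true_subgroup).rename("subgroup").to_csv(
            out / "truth_subgroups.tsv", sep="\t"
        )
    if ztable is None:
        ztable = make_survival_ztable(references, seed=config.seed)
    counts.to_tsv(out / "counts.tsv")
    ann.to_tsv(out / "annotation.tsv")

    log.info("stage=tpm genes=%d samples=%d", *counts.shape)
    tpm = tpm_from_counts(counts, ann)
    tpm.to_tsv(out / "tpm.tsv")

    tam_all = [s for s in tpm.sample_ids if s.startswith("TAM")]
    tum = [s for s in tpm.sample_ids if s.startswith("TUM")]
    tat = [s for s in tpm.sample_ids if s.startswith("TAT")]
    if not tam_all:
        raise ValueError("no TAM samples in the matrix (sample ids must start TAM)")
    tam_tpm = tpm.subset_samples(tam_all)

    epcam = ann.symbol_to_gene("EPCAM")
    msln = ann.symbol_to_gene("MSLN")
    excluded = purity.flag_contaminated_samples(
        tam_tpm, [epcam, msln], threshold=config.contamination_marker_tpm
    )
    retained = [s for s in tam_all if s not in excluded]
    log.info("stage=qc excluded=%s", excluded)
    if not retained:
        raise ValueError("QC excluded every TAM sample (all EPCAM/MSLN > threshold)")
    io.write_gene_list(excluded, out / "excluded_samples.tsv")
    tam_tpm = tam_tpm.subset_samples(retained)

    markers = _tumor_marker_ids(ann)
    tumor_ref = references.profiles["tumor"]
    corrected, estimates = purity.correct_matrix(tam_tpm, tumor_ref, markers)
    est_df = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "fraction": [e.fraction for e in estimates],
            "residual": [e.residual for e in estimates],
            "n_markers": [len(e.marker_genes_used) for e in estimates],
        }
    ).set_index("sample_id")
    est_df.to_csv(out / "contamination.tsv", sep="\t")
    log.info("stage=correct mean_f=%.3f", est_df["fraction"].mean())

    expressed = filter_expressed(
        corrected, threshold=config.expressed_tpm, min_samples=config.expressed_min_samples
    )
    blacklist = []
    if tum and tat:
        blacklist = purity.blacklist_crosscell_genes(
            tpm.subset_samples(retained),
            tpm.subset_samples(tum),
            tpm.subset_samples(tat),
            fold=config.crosscell_fold,
            pseudocount=config.crosscell_pseudocount,
        )
    keep = [g for g in expressed if g not in set(blacklist)]
    log.info("stage=filter expressed=%d blacklisted=%d kept=%d",
             len(expressed), len(blacklist), len(keep))
    io.write_gene_list(blacklist, out / "blacklist.tsv")
    analysis_tpm = corrected.subset_genes(keep)

    normalized = genewise_normalize(analysis_tpm)
    coords = stratify.pca_project(normalized)
    marker_gene = ann.symbol_to_gene(config.marker_symbol)
    assignments = stratify.assign_subgroups(corrected, marker_gene, coords=coords)
    groups = {a.sample_id: a.label for a in assignments}
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id, "label": a.label,
                "pc1": a.pc1, "pc2": a.pc2, "marker_tpm": a.marker_tpm,
            }
            for a in assignments
        ]
    ).set_index("sample_id").to_csv(out / "subgroups.tsv", sep="\t")
    order = sorted(retained, key=lambda s: (groups[s], s))
    stratify.sample_correlation(normalized, order=order).to_csv(
        out / "sample_correlation.tsv", sep="\t"
    )
    log.info("stage=stratify A=%d B=%d",
             sum(v == "A" for v in groups.values()),
             sum(v == "B" for v in groups.values()))

    # DE on contamination-corrected pseudo-counts at the sample's library size
    lib = counts.subset_samples(retained).data.sum(axis=0)
    lengths = ann.lengths(keep).to_numpy(dtype=float)
    w = analysis_tpm.data.to_numpy() * lengths[:, None]
    pseudo = np.rint(w / w.sum(axis=0, keepdims=True) * lib.to_numpy()[None, :])
    pseudo_counts = ExpressionMatrix(
        pd.DataFrame(pseudo, index=keep, columns=retained).astype(np.int64), "counts"
    )
    results = diffexp.de_table(pseudo_counts, analysis_tpm, groups, fdr_threshold=config.fdr)
    results.to_csv(out / "de_results.tsv", sep="\t")
    sig_a, sig_b = diffexp.define_signatures(results, fdr_threshold=config.fdr)
    io.write_gmt([sig_a, sig_b], out / "signatures.gmt")
    log.info("stage=de signature_A=%d signature_B=%d", len(sig_a.genes), len(sig_b.genes))

    # variance ranking on the TPM scale; correlations on genewise-normalized
    k = min(config.k_top_variance, normalized.shape[0])
    candidates = coexpress.top_variance_genes(analysis_tpm, k=k)
    combined = coexpress.correlation_sets(
        normalized, candidates, r_min=config.r_min, min_size=config.min_set_size
    )
    result = coexpress.cluster_genes(normalized, combined, cut_height=config.cut_height)
    _, partition = coexpress.cluster_samples(normalized, combined)
    cluster_sets = [
        diffexp.SignatureSet(
            f"cluster_{lab}",
            tuple(g for g in combined if result.gene_cluster[g] == lab),
            "none",
        )
        for lab in sorted(result.cluster_sizes)
    ]
    io.write_gmt(cluster_sets, out / "coexpression_clusters.gmt")
    overlaps = []
    for cs in cluster_sets:
        for sig in (sig_a, sig_b):
            if not sig.genes:
                continue
            st = coexpress.signature_overlap(cs, sig)
            overlaps.append(asdict(st))
    pd.DataFrame(overlaps).to_csv(out / "overlaps.tsv", sep="\t", index=False)
    log.info("stage=coexpress combined=%d clusters=%s", len(combined), result.cluster_sizes)

    io.write_ztable(ztable, out / "survival_z.tsv")
    scored_sets = [s for s in (sig_a, sig_b) if s.genes]
    surv = survival.summarize_signatures(
        ztable, scored_sets, n_perm=config.n_perm, seed=config.seed,
        threshold=config.favorable_z,
    )
    surv.to_csv(out / "survival_summary.tsv", sep="\t")
    log.info("stage=survival %s", surv["mean_z"].to_dict())

    report = RunReport(
        seed=config.seed,
        n_genes=counts.shape[0],
        tam_samples=tam_all,
        excluded_samples=excluded,
        contamination=est_df["fraction"].to_dict(),
        n_expressed=len(expressed),
        blacklist=blacklist,
        subgroup=groups,
        n_signature_a=len(sig_a.genes),
        n_signature_b=len(sig_b.genes),
        cluster_sizes=result.cluster_sizes,
        n_combined_genes=len(combined),
        sample_partition=partition,
        overlaps=overlaps,
        survival_summary=surv.to_dict(orient="index"),
    )
    report.to_json(out / "report.json")
    resolved = asdict(config)
    (out / "config.json").write_text(json.dumps(resolved, indent=2, sort_keys=True))
    return report
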
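"""Shared fixtures: small synthetic cohorts and toy matrices."""

import numpy as np
import pandas as pd
import pytest

from tamstrat import (
    ExpressionMatrix,
    GeneAnnotation,
    SimulationConfig,
    generate_cohort,
    generate_references,
    tpm_from_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact cohort: 4+4 TAM samples, two signature modules, one neutral."""
    return SimulationConfig(
        n_genes=600,
        n_tam_per_subgroup=4,
        n_tumor_samples=3,
        n_tat_samples=3,
        module_sizes=(15, 15, 12),
        n_tumor_markers=8,
        library_size_mean=1_000_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    refs = generate_references(small_config)
    counts, truth = generate_cohort(small_config, refs)
    return refs, counts, truth


@pytest.fixture(scope="session")
def small_tam_tpm(small_cohort):
    refs, counts, truth = small_cohort
    tam = counts.subset_samples(sorted(truth.true_subgroup))
    return tpm_from_counts(tam, refs.annotation)


@pytest.fixture()
def toy_annotation() -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": ["A1", "B1", "C1"],
                "length_bp": [100, 200, 1000],
                "biotype": ["protein_coding"] * 3,
                "marker_role": ["none"] * 3,
            },
            index=["g1", "g2", "g3"],
        )
    )


def make_matrix(values, genes=None, samples=None, unit="counts") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


@pytest.fixture()
def matrix_factory():
    return make_matrix
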
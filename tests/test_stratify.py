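"""PCA projection, marker-median subgrouping, correlation structure and
group statistics."""

import numpy as np
import pandas as pd
import pytest

from tamstrat import (
    assign_subgroups,
    bootstrap_ci,
    compare_groups,
    pca_project,
    sample_correlation,
    significance_stars,
)
from tamstrat.expression import TPM_TOTAL, ExpressionMatrix


def _tpm(df: pd.DataFrame) -> ExpressionMatrix:
    df = df / df.sum(axis=0) * TPM_TOTAL
    return ExpressionMatrix(df.astype(float), "tpm")


class TestPca:
    def test_rank_one_data_loads_on_pc1(self, matrix_factory):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=30)
        scores = rng.normal(size=6)
        vals = np.outer(direction, scores)
        m = matrix_factory(vals - vals.min() + 1.0, unit="counts")
        coords = pca_project(m, n_components=2, whiten=False)
        var = coords.var(axis=0, ddof=1)
        assert var["pc1"] / var.sum() > 0.99

    def test_duplicated_samples_coincide(self, matrix_factory):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2, 10, (40, 5))
        vals = np.column_stack([vals, vals[:, 2]])
        coords = pca_project(matrix_factory(vals), whiten=False)
        np.testing.assert_allclose(coords.iloc[2], coords.iloc[5], atol=1e-8)

    def test_projection_matches_eigendecomposition(self, matrix_factory):
        # independent oracle: eigenvectors of the gene-centered covariance
        rng = np.random.default_rng(2)
        vals = rng.gamma(2, 10, (25, 8))
        m = matrix_factory(vals)
        n = 8
        coords = pca_project(m, n_components=n - 1, whiten=False)
        X = vals.T - vals.T.mean(axis=0)  # samples x genes, gene-centered
        evals, evecs = np.linalg.eigh(X.T @ X / (n - 1))
        order = np.argsort(evals)[::-1]
        for j in range(n - 1):
            v = evecs[:, order[j]]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(coords.iloc[:, j], X @ v, atol=1e-8)
        # reconstruction from all components returns the centered data
        recon = sum(
            np.outer(coords.iloc[:, j], evecs[:, order[j]] * np.sign(
                evecs[np.argmax(np.abs(evecs[:, order[j]])), order[j]]))
            for j in range(n - 1)
        )
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_too_few_samples(self, matrix_factory):
        with pytest.raises(ValueError):
            pca_project(matrix_factory(np.ones((5, 2))))


class TestAssignSubgroups:
    def _matrix(self, cd163):
        n = len(cd163)
        df = pd.DataFrame(
            [cd163, [TPM_TOTAL] * n],
            index=["CD163", "rest"],
            columns=[f"s{i}" for i in range(n)],
            dtype=float,
        )
        return _tpm(df)

    def test_top_half_labeled_a(self):
        m = self._matrix([10, 20, 30, 100, 200, 300])
        labels = {a.sample_id: a.label for a in assign_subgroups(m, "CD163")}
        assert [labels[f"s{i}"] for i in range(6)] == ["B"] * 3 + ["A"] * 3

    def test_sample_at_median_goes_to_b(self):
        m = self._matrix([10.0, 20.0, 30.0])
        labels = {a.sample_id: a.label for a in assign_subgroups(m, "CD163")}
        assert labels["s1"] == "B"  # exactly the median: strict > required

    def test_margin_voids_near_median_labels(self):
        m = self._matrix([10.0, 20.0, 21.0, 300.0])
        out = {a.sample_id: a.label
               for a in assign_subgroups(m, "CD163", margin=5.0)}
        assert out["s1"] == "unassigned" and out["s2"] == "unassigned"
        assert out["s0"] == "B" and out["s3"] == "A"

    def test_missing_marker(self):
        with pytest.raises(KeyError):
            assign_subgroups(self._matrix([1.0, 2.0]), "CD68")

    def test_recovery_degrades_gracefully_at_twofold_marker(self):
        # at a 2-fold (rather than 4-fold) subgroup effect the marker-median
        # rule still recovers most of the planted labels (ARI >= 0.6), when
        # marker noise stays at the count level (weak module factor): a large
        # shared factor would by construction drown a 2-fold shift
        from sklearn.metrics import adjusted_rand_score

        from tamstrat import (
            SimulationConfig,
            generate_cohort,
            generate_references,
            tpm_from_counts,
        )

        aris = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_genes=800, de_log2_effect=1.0, contamination_fractions=[0.0],
                n_tumor_samples=0, n_tat_samples=0, module_correlation=0.4,
                seed=seed,
            )
            refs = generate_references(cfg)
            counts, truth = generate_cohort(cfg, refs)
            tpm = tpm_from_counts(
                counts.subset_samples(sorted(truth.true_subgroup)), refs.annotation
            )
            marker = refs.annotation.symbol_to_gene("CD163")
            labels = {a.sample_id: a.label for a in assign_subgroups(tpm, marker)}
            samples = sorted(labels)
            aris.append(
                adjusted_rand_score(
                    [truth.true_subgroup[s] for s in samples],
                    [labels[s] for s in samples],
                )
            )
        assert np.mean(aris) >= 0.6

    def test_even_cohort_without_ties_splits_in_half(self):
        rng = np.random.default_rng(3)
        vals = rng.permutation(np.arange(1.0, 13.0))
        labels = [a.label for a in assign_subgroups(self._matrix(vals), "CD163")]
        assert labels.count("A") == 6


class TestSampleCorrelation:
    def test_diagonal_and_antisymmetry(self, matrix_factory):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        m = matrix_factory(np.column_stack([x, -x + 10.0]), unit="normalized")
        corr = sample_correlation(m)
        assert corr.iloc[0, 0] == pytest.approx(1.0)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_three_by_three_hand_oracle(self, matrix_factory):
        vals = np.array([[1.0, 2.0, 0.0], [4.0, 1.0, 2.0], [2.0, 3.0, 5.0]])
        corr = sample_correlation(matrix_factory(vals))
        for i in range(3):
            for j in range(3):
                a, b = vals[:, i], vals[:, j]
                expect = (
                    ((a - a.mean()) * (b - b.mean())).sum()
                    / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
                )
                assert corr.iloc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_permutation_permutes_rows(self, matrix_factory):
        rng = np.random.default_rng(4)
        m = matrix_factory(rng.gamma(2, 5, (30, 4)))
        c1 = sample_correlation(m)
        order = ["s3", "s1", "s4", "s2"]
        c2 = sample_correlation(m, order=order)
        np.testing.assert_allclose(c2, c1.loc[order, order], rtol=1e-12)

    def test_constant_sample_named(self, matrix_factory):
        vals = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        with pytest.raises(ValueError, match="s2"):
            sample_correlation(matrix_factory(vals))


class TestCompareGroups:
    def test_identical_groups_null(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_student_t(self):
        # pooled var 1, se = sqrt(2/3), t = -3/se = -3.674, df 4 -> p = 0.0213
        t, p = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(0.021312, abs=5e-6)

    def test_swap_negates_t_keeps_p(self):
        t1, p1 = compare_groups([1.0, 2.0, 4.0], [5.0, 6.0, 9.0])
        t2, p2 = compare_groups([5.0, 6.0, 9.0], [1.0, 2.0, 4.0])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_paired_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.2) == "ns"


class TestBootstrap:
    def test_constant_data_zero_width(self):
        lo, hi = bootstrap_ci([5.0] * 10, seed=0)
        assert lo == hi == 5.0

    def test_seed_determinism(self):
        data = list(np.random.default_rng(0).normal(size=30))
        assert bootstrap_ci(data, seed=3) == bootstrap_ci(data, seed=3)

    def test_level_bounds(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0], level=120)

    def test_coverage_of_median_ci(self):
        # 95% CI of the median over repeated normal samples covers 0 ~95%
        rng = np.random.default_rng(12)
        cover = 0
        n_sim = 500
        for i in range(n_sim):
            data = rng.normal(size=200)
            lo, hi = bootstrap_ci(data, n_boot=400, seed=int(rng.integers(2**31)))
            cover += lo <= 0 <= hi
        assert 0.93 <= cover / n_sim <= 0.97
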
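"""Variance ranking, correlation-set combination, WPGMA clustering (with a
brute-force agglomeration oracle) and signature overlaps."""

import numpy as np
import pandas as pd
import pytest

from tamstrat import (
    SignatureSet,
    cluster_genes,
    cluster_samples,
    correlation_sets,
    signature_overlap,
    top_variance_genes,
)
from tamstrat.expression import ExpressionMatrix


def _matrix(vals, genes=None, unit="normalized"):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i + 1:03d}" for i in range(vals.shape[0])]
    cols = [f"s{j + 1}" for j in range(vals.shape[1])]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols), unit)


def planted_matrix(seed, n_noise=500, module_sizes=(15,), rho=0.95, n_samples=18):
    """Gaussian latent-factor modules amid independent noise."""
    rng = np.random.default_rng(seed)
    blocks = []
    genes = []
    truth = {}
    for m, size in enumerate(module_sizes, start=1):
        factor = rng.normal(size=n_samples)
        block = (
            np.sqrt(rho) * factor[None, :]
            + np.sqrt(1 - rho) * rng.normal(size=(size, n_samples))
        )
        blocks.append(block)
        ids = [f"mod{m}_{j:03d}" for j in range(size)]
        genes += ids
        truth.update({g: m for g in ids})
    blocks.append(rng.normal(size=(n_noise, n_samples)))
    genes += [f"noise{j:04d}" for j in range(n_noise)]
    return _matrix(np.vstack(blocks), genes=genes), truth


def brute_force_wpgma(dist: np.ndarray):
    """Textbook WPGMA agglomeration; ties broken by smallest pair indices.

    Returns rows (id_a, id_b, height, size) with scipy's new-cluster ids.
    """
    n = dist.shape[0]
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    active = {i: 1 for i in range(n)}  # id -> leaf count
    merges = []
    next_id = n
    while len(active) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        size = active[a] + active[b]
        merges.append((a, b, h, size))
        del active[a], active[b]
        for c in list(active):
            da = d.pop((min(a, c), max(a, c)))
            db = d.pop((min(b, c), max(b, c)))
            d[(c, next_id)] = (da + db) / 2.0  # weighted: mean of children
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        active[next_id] = size
        next_id += 1
    return merges


class TestTopVariance:
    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.gamma(2, 10, (10, 6)))
        var = m.data.var(axis=1, ddof=1)
        expect = sorted(m.gene_ids, key=lambda g: (-var[g], g))
        assert top_variance_genes(m, k=10) == expect
        assert top_variance_genes(m, k=4) == expect[:4]

    def test_constant_genes_rank_last(self):
        vals = np.vstack([np.full(6, 3.0), np.random.default_rng(1).normal(size=(3, 6))])
        m = _matrix(vals, genes=["flat", "a", "b", "c"])
        assert top_variance_genes(m, k=4)[-1] == "flat"

    def test_bad_k(self):
        m = _matrix(np.ones((3, 4)))
        with pytest.raises(ValueError):
            top_variance_genes(m, k=0)
        with pytest.raises(ValueError):
            top_variance_genes(m, k=5)


class TestCorrelationSets:
    def test_planted_module_recovered_exactly(self):
        m, truth = planted_matrix(seed=0, module_sizes=(15,))
        combined = correlation_sets(m, m.gene_ids, r_min=0.89, min_size=10)
        assert combined == sorted(truth)

    def test_pure_noise_yields_empty_set(self):
        m, _ = planted_matrix(seed=1, module_sizes=())
        assert correlation_sets(m, m.gene_ids) == []

    def test_degenerate_thresholds_return_everything(self):
        m, _ = planted_matrix(seed=2, n_noise=30, module_sizes=())
        assert correlation_sets(m, m.gene_ids, r_min=-1.0, min_size=0) == sorted(m.gene_ids)

    def test_constant_gene_excluded_with_warning(self):
        vals = np.vstack([np.full(12, 2.0), np.random.default_rng(3).normal(size=(20, 12))])
        m = _matrix(vals)
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_sets(m, m.gene_ids)
        assert "g001" not in out

    def test_monotone_in_r_min(self):
        m, _ = planted_matrix(seed=4, n_noise=100, module_sizes=(12, 12), rho=0.9)
        sizes = [
            len(correlation_sets(m, m.gene_ids, r_min=r, min_size=5))
            for r in (0.5, 0.7, 0.89, 0.97)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestClusterGenes:
    def test_two_planted_modules_split_exactly(self):
        m, truth = planted_matrix(seed=5, n_noise=0, module_sizes=(15, 20))
        res = cluster_genes(m, sorted(truth), cut_height=0.8)
        # relabeled by size: module 2 (20 genes) -> I, module 1 -> II
        assert res.cluster_sizes == {"I": 20, "II": 15}
        for g, lab in res.gene_cluster.items():
            assert lab == ("I" if truth[g] == 2 else "II")

    def test_single_module_single_cluster(self):
        m, truth = planted_matrix(seed=6, n_noise=0, module_sizes=(12,))
        res = cluster_genes(m, sorted(truth))
        assert res.cluster_sizes == {"I": 12}

    def test_merge_sequence_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            vals = rng.normal(size=(6, 12))
            m = _matrix(vals)
            res = cluster_genes(m, m.gene_ids, cut_height=0.8)
            corr = np.corrcoef(vals)
            oracle = brute_force_wpgma(1.0 - corr)
            for row, (a, b, h, size) in zip(res.linkage_tree, oracle):
                assert sorted(row[:2].astype(int)) == sorted((a, b))
                assert row[2] == pytest.approx(h, rel=1e-9)
                assert int(row[3]) == size

    def test_cut_extremes(self):
        m, truth = planted_matrix(seed=9, n_noise=0, module_sizes=(8, 8))
        singles = cluster_genes(m, sorted(truth), cut_height=0.0)
        assert len(singles.cluster_sizes) == 16
        one = cluster_genes(m, sorted(truth), cut_height=2.0)
        assert len(one.cluster_sizes) == 1

    def test_empty_combined_set_advises(self):
        m, _ = planted_matrix(seed=10, n_noise=5, module_sizes=())
        with pytest.raises(ValueError, match="relax"):
            cluster_genes(m, [])


class TestClusterSamples:
    def test_duplicate_sample_merges_at_zero_height(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(30, 5))
        vals = np.column_stack([vals, vals[:, 0]])
        m = _matrix(vals)
        tree, _ = cluster_samples(m, m.gene_ids)
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(tree[0, :2].astype(int)) == [0, 5]

    def test_partition_invariant_to_sample_order(self):
        m, truth = planted_matrix(seed=12, n_noise=50, module_sizes=(15,))
        _, part1 = cluster_samples(m, sorted(truth))
        perm = list(np.random.default_rng(0).permutation(m.sample_ids))
        m2 = m.subset_samples(perm)
        _, part2 = cluster_samples(m2, sorted(truth))
        same = all(
            (part1[a] == part1[b]) == (part2[a] == part2[b])
            for a in m.sample_ids
            for b in m.sample_ids
        )
        assert same


class TestSignatureOverlap:
    def test_worked_percentages(self):
        x = SignatureSet("cluster_I", tuple(f"g{i}" for i in range(140)), "none")
        y = SignatureSet(
            "signature_A", tuple(f"g{i}" for i in range(120)) + ("h1", "h2"), "up_in_A"
        )
        stat = signature_overlap(x, y)
        assert stat.n_intersection == 120
        assert stat.pct_of_x == 85.7

    def test_second_worked_example(self):
        x = SignatureSet("cluster_III", tuple(f"g{i}" for i in range(266)), "none")
        y = SignatureSet("signature_B", tuple(f"g{i}" for i in range(148)), "up_in_B")
        assert signature_overlap(x, y).pct_of_x == 55.6

    def test_disjoint_sets(self):
        x = SignatureSet("x", ("a", "b"), "none")
        y = SignatureSet("y", ("c",), "none")
        stat = signature_overlap(x, y)
        assert stat.n_intersection == 0 and stat.pct_of_x == 0.0

    def test_empty_set_rejected(self):
        x = SignatureSet("x", ("a",), "none")
        y = SignatureSet("y", (), "none")
        with pytest.raises(ValueError):
            signature_overlap(x, y)
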
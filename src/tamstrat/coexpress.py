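"""Coexpression-module detection by correlation thresholding and clustering.

The procedure: rank genes by expression variance, keep the top k (3000 in
the study); for each candidate gene collect its correlation neighborhood
(Pearson r > 0.89) and keep neighborhoods larger than 10 genes; the union of
kept neighborhoods is the combined coexpressed gene set. The combined genes
are clustered by weighted-average (WPGMA) agglomeration on correlation
distance ``d = 1 - r`` and the dendrogram is cut at height 0.8, yielding the
gene clusters (labeled I, II, III, ... by descending size). The same linkage
applied to samples over the combined genes gives the two-branch patient
partition, and cluster/signature intersections quantify the agreement of the
coexpression and differential-expression views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .diffexp import SignatureSet
from .expression import ExpressionMatrix


@dataclass
class CoexpressionResult:
    combined_genes: list[str]
    gene_cluster: dict[str, str]  # gene -> roman cluster label
    linkage_tree: np.ndarray  # scipy linkage matrix over combined genes
    cluster_sizes: dict[str, int]


@dataclass
class OverlapStat:
    set_x_name: str
    set_y_name: str
    n_x: int
    n_y: int
    n_intersection: int
    pct_of_x: float

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.n_x, self.n_y):
            raise ValueError("intersection larger than a set")


def top_variance_genes(matrix: ExpressionMatrix, k: int = 3000) -> list[str]:
    """The k genes with greatest sample variance, descending; ties by gene id."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {matrix.shape[0]}")
    var = matrix.data.var(axis=1, ddof=1)
    order = sorted(matrix.gene_ids, key=lambda g: (-var[g], g))
    return order[:k]


def correlation_sets(
    matrix: ExpressionMatrix,
    candidate_genes: list[str],
    r_min: float = 0.89,
    min_size: int = 10,
) -> list[str]:
    """Union of correlation neighborhoods: the combined coexpressed gene set.

    For each candidate gene g, ``S(g) = {g' != g : r(g, g') > r_min}``; genes
    with ``|S(g)| > min_size`` contribute ``S(g) | {g}``. Both thresholds are
    strict. Constant gene rows are excluded with a warning (their correlation
    is undefined). The result is deduplicated and sorted by gene id.
    """
    if matrix.shape[1] < 3:
        raise ValueError("correlation sets require >= 3 samples")
    missing = [g for g in candidate_genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {missing[:5]}")
    sub = matrix.data.loc[candidate_genes]
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        dropped = sub.index[sd == 0].tolist()
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s) with undefined correlation",
            stacklevel=2,
        )
        sub = sub.loc[sd > 0]
        vals = sub.to_numpy(dtype=float)
    corr = np.corrcoef(vals)
    np.fill_diagonal(corr, 0.0)  # a gene is not its own neighbor
    neighbor = corr > r_min
    keep = neighbor.sum(axis=1) > min_size
    combined: set[str] = set()
    genes = np.array(sub.index)
    for i in np.flatnonzero(keep):
        combined.add(genes[i])
        combined.update(genes[neighbor[i]])
    return sorted(combined)


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for val, sym in numerals:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def _relabel_by_size(genes: list[str], flat: np.ndarray) -> dict[str, str]:
    """Deterministic cluster labels: descending size, ties by smallest member."""
    by_id: dict[int, list[str]] = {}
    for g, c in zip(genes, flat):
        by_id.setdefault(int(c), []).append(g)
    ordered = sorted(by_id.values(), key=lambda members: (-len(members), min(members)))
    labels = {}
    for rank, members in enumerate(ordered, start=1):
        for g in members:
            labels[g] = _roman(rank)
    return labels


def cluster_genes(
    matrix: ExpressionMatrix,
    combined_genes: list[str],
    cut_height: float = 0.8,
) -> CoexpressionResult:
    """WPGMA clustering of genes on correlation distance, cut at a fixed height.

    Uses weighted linkage (the merged node's distance to any other node is
    the mean of its two children's distances) with metric ``1 - r``; flat
    clusters come from cutting the tree at ``cut_height`` and are relabeled
    I, II, ... by descending size.
    """
    if not combined_genes:
        raise ValueError(
            "empty combined gene set: relax r_min/min_size before clustering"
        )
    if len(combined_genes) < 2:
        raise ValueError("need >= 2 combined genes to cluster")
    sub = matrix.data.loc[combined_genes].to_numpy(dtype=float)
    tree = linkage(sub, method="weighted", metric="correlation")
    flat = fcluster(tree, t=cut_height, criterion="distance")
    labels = _relabel_by_size(list(combined_genes), flat)
    sizes: dict[str, int] = {}
    for lab in labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    return CoexpressionResult(
        combined_genes=list(combined_genes),
        gene_cluster=labels,
        linkage_tree=tree,
        cluster_sizes=sizes,
    )


def cluster_samples(
    matrix: ExpressionMatrix, combined_genes: list[str]
) -> tuple[np.ndarray, dict[str, int]]:
    """Two-branch sample partition by the same WPGMA/correlation linkage.

    Returns the sample linkage tree and a mapping sample -> branch id (1/2),
    from clustering sample profiles restricted to the combined genes.
    """
    if matrix.shape[1] < 2:
        raise ValueError("sample clustering requires >= 2 samples")
    sub = matrix.data.loc[combined_genes].to_numpy(dtype=float).T
    tree = linkage(sub, method="weighted", metric="correlation")
    flat = fcluster(tree, t=2, criterion="maxclust")
    return tree, dict(zip(matrix.sample_ids, (int(c) for c in flat)))


def signature_overlap(set_x: SignatureSet, set_y: SignatureSet) -> OverlapStat:
    """Intersection count and percent-of-x between two gene sets.

    ``pct_of_x = 100 * |x & y| / |x|``, reported to one decimal — e.g. a
    140-gene cluster sharing 120 genes with a signature overlaps 85.7%.
    """
    if not set_x.genes or not set_y.genes:
        raise ValueError("overlap of an empty gene set is undefined")
    inter = len(set(set_x.genes) & set(set_y.genes))
    return OverlapStat(
        set_x_name=set_x.name,
        set_y_name=set_y.name,
        n_x=len(set_x.genes),
        n_y=len(set_y.genes),
        n_intersection=inter,
        pct_of_x=round(100.0 * inter / len(set_x.genes), 1),
    )
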
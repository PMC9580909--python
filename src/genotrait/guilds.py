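"""Functional guild discovery from mixed-type trait matrices.

Genome-to-genome dissimilarity uses a Wishart-style mixed-type distance: a
Gower-family metric that weights numeric variables by their variance
(rather than their range) and uses squared distance components,

    d_ij = sqrt( (1/p) [ Σ_numeric (x_ik − x_jk)² / s_k²
                       + Σ_binary  1[x_ik ≠ x_jk] ] ),

with s_k² the sample variance of column k and p the number of variables
entering the sum. Because a 0/1 mismatch indicator equals the squared
difference of the binary codes, d² is a (scaled) squared Euclidean
distance, which makes the downstream variance partitioning well behaved.

Genomes are clustered by complete-linkage agglomeration; cutting the tree
at every k from 1 to n and partitioning the squared distances into within-
and between-cluster sums (the PERMANOVA decomposition) yields the variance
curve R²(k), from which guilds are defined at a fixed k or at the smallest
k explaining a target variance fraction. Guild profiles report trait
positivity (binary) or mean per-bp investment (count) per guild, with a
Kruskal–Wallis across-guild test per trait and Benjamini–Hochberg
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, spearmanr
from statsmodels.stats.multitest import multipletests

from .traits import TraitMatrix

__all__ = [
    "DistanceMatrix",
    "GuildAssignment",
    "GuildProfile",
    "wishart_distance",
    "hierarchical_cluster",
    "variance_curve",
    "define_guilds",
    "guild_profiles",
    "trait_correlations",
    "dendrogram_to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric genome × genome distances plus the numeric variance weights used."""

    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal
    variance_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square over the genome ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="genome"
        )


@dataclass
class GuildAssignment:
    """Genome → guild labels (1..k) for one tree cut, with small-guild flags."""

    labels: pd.Series  # index: genome ids, values: 1..k
    k: int
    flagged_small: list[int] = field(default_factory=list)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class GuildProfile:
    """Per-guild trait means, across-guild test results, life-history quantiles."""

    means: pd.DataFrame  # guilds × traits (positivity for binary traits)
    pvalues: pd.Series  # per trait, Kruskal-Wallis across guilds (NaN if untestable)
    qvalues: pd.Series  # Benjamini-Hochberg adjusted
    life_history: pd.DataFrame | None = None  # (guild, statistic) × life-history column


def wishart_distance(matrix: TraitMatrix) -> DistanceMatrix:
    """Mixed-type Wishart distance over a trait matrix.

    Numeric (count) columns contribute squared differences weighted by the
    inverse sample variance (ddof=1); binary columns contribute mismatch
    indicators. Zero-variance numeric columns are dropped with a warning;
    if every column is constant the result is the all-zero matrix.
    """
    if matrix.data.shape[0] < 2:
        raise ValueError("need at least 2 genomes")
    ids = matrix.genome_ids
    n = len(ids)

    numeric_cols = matrix.columns_of_type("count")
    binary_cols = matrix.columns_of_type("binary")

    weights: dict[str, float] = {}
    kept_numeric = []
    for c in numeric_cols:
        s2 = float(np.var(matrix.data[c].to_numpy(dtype=float), ddof=1))
        if s2 == 0.0:
            warnings.warn(f"numeric trait {c!r} is constant; dropped from distance")
            continue
        weights[c] = s2
        kept_numeric.append(c)

    d2 = np.zeros((n, n))
    p = len(kept_numeric) + len(binary_cols)
    if kept_numeric:
        x = matrix.data[kept_numeric].to_numpy(dtype=float)
        x = x / np.sqrt(np.array([weights[c] for c in kept_numeric]))
        d2 += squareform(pdist(x, metric="sqeuclidean"))
    if binary_cols:
        b = matrix.data[binary_cols].to_numpy(dtype=float)
        d2 += squareform(pdist(b, metric="sqeuclidean"))  # 0/1 mismatch count
    if p == 0:
        warnings.warn("all trait columns constant; distance matrix is zero")
        return DistanceMatrix(ids=ids, values=d2, variance_weights=weights)
    d = np.sqrt(np.maximum(d2 / p, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, values=d, variance_weights=weights)


def hierarchical_cluster(d: DistanceMatrix) -> np.ndarray:
    """Complete-linkage agglomeration; returns a scipy linkage matrix."""
    if d.n < 2:
        raise ValueError("need at least 2 genomes to cluster")
    return sch.linkage(d.condensed, method="complete")


def _cut_labels(linkage: np.ndarray, k: int) -> np.ndarray:
    """k-cluster tree cut, relabeled 1..k by first appearance for determinism."""
    raw = sch.cut_tree(linkage, n_clusters=k).ravel()
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def partition_r2(d: DistanceMatrix, labels: Sequence[int]) -> float:
    """Fraction of squared-distance variance explained by a partition.

    SS_total = (1/n) Σ_{i<j} d_ij²; SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²;
    R² = 1 − SS_within / SS_total (the PERMANOVA decomposition).
    """
    labels = np.asarray(labels)
    v2 = d.values**2
    n = d.n
    iu = np.triu_indices(n, 1)
    ss_total = v2[iu].sum() / n
    if ss_total == 0.0:
        raise ValueError("total sum of squares is zero; variance curve undefined")
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = v2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return 1.0 - ss_within / ss_total


def variance_curve(d: DistanceMatrix, linkage: np.ndarray) -> pd.DataFrame:
    """R²(k) for every k-cluster cut of the tree, k = 1..n.

    Nested complete-linkage cuts refine as k grows, so R² is non-decreasing,
    with R²(1) = 0 and R²(n) = 1.
    """
    n = d.n
    rows = []
    for k in range(1, n + 1):
        labels = _cut_labels(linkage, k)
        rows.append({"k": k, "r2": partition_r2(d, labels)})
    return pd.DataFrame(rows)


def define_guilds(
    d: DistanceMatrix,
    linkage: np.ndarray,
    curve: pd.DataFrame | None = None,
    k: int | None = None,
    variance_target: float | None = None,
    min_size: int = 1,
) -> GuildAssignment:
    """Assign genomes to guilds at a fixed k or a variance target.

    With ``variance_target`` v, k is the smallest cut with R²(k) ≥ v.
    Guilds smaller than ``min_size`` are flagged (kept, not removed).
    """
    if (k is None) == (variance_target is None):
        raise ValueError("specify exactly one of k or variance_target")
    if variance_target is not None:
        if curve is None:
            curve = variance_curve(d, linkage)
        ok = curve[curve["r2"] >= variance_target - 1e-12]
        if ok.empty:
            raise ValueError(
                f"variance target {variance_target} unachievable "
                f"(max R² = {curve['r2'].max():.4f})"
            )
        k = int(ok["k"].iloc[0])
    assert k is not None
    if not (1 <= k <= d.n):
        raise ValueError(f"k = {k} outside 1..{d.n}")
    labels = pd.Series(_cut_labels(linkage, k), index=d.ids, name="guild")
    sizes = labels.value_counts()
    flagged = sorted(int(g) for g, size in sizes.items() if size < min_size)
    return GuildAssignment(labels=labels, k=k, flagged_small=flagged)


def guild_profiles(
    assignment: GuildAssignment,
    matrix: TraitMatrix,
    life_history: pd.DataFrame | None = None,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
) -> GuildProfile:
    """Trait profile per guild: positivity/mean, across-guild tests, life history.

    The across-guild test is a Kruskal–Wallis rank test per trait with
    Benjamini–Hochberg adjustment across traits; traits constant across all
    genomes, or with fewer than two guilds, get NaN p-values.
    """
    if not set(matrix.genome_ids) <= set(assignment.labels.index):
        raise ValueError("assignment does not cover all genomes in the matrix")
    labels = assignment.labels.loc[matrix.genome_ids]
    means = matrix.data.groupby(labels).mean()
    means.index.name = "guild"

    pvals = {}
    groups_idx = [labels[labels == g].index for g in sorted(labels.unique())]
    for trait in matrix.data.columns:
        groups = [matrix.data.loc[idx, trait].to_numpy(dtype=float) for idx in groups_idx]
        groups = [g for g in groups if len(g)]
        values = matrix.data[trait].to_numpy(dtype=float)
        if len(groups) < 2 or np.all(values == values[0]):
            pvals[trait] = np.nan
            continue
        try:
            pvals[trait] = float(kruskal(*groups).pvalue)
        except ValueError:  # all values identical within the test
            pvals[trait] = np.nan
    pvalues = pd.Series(pvals, name="pvalue")
    qvalues = pd.Series(np.nan, index=pvalues.index, name="qvalue")
    testable = pvalues.notna()
    if testable.any():
        qvalues[testable] = multipletests(pvalues[testable], method="fdr_bh")[1]

    lh = None
    if life_history is not None:
        lh_labels = assignment.labels.loc[life_history.index]
        parts = []
        for q in quantiles:
            part = life_history.groupby(lh_labels).quantile(q)
            part.index = pd.MultiIndex.from_product(
                [part.index, [q]], names=["guild", "quantile"]
            )
            parts.append(part)
        lh = pd.concat(parts).sort_index()
    return GuildProfile(means=means, pvalues=pvalues, qvalues=qvalues, life_history=lh)


def trait_correlations(matrix: TraitMatrix) -> pd.DataFrame:
    """Spearman rank correlation between every trait pair.

    Constant traits have undefined rank correlation and yield NaN rows and
    columns (diagonal included, flagging them explicitly).
    """
    if matrix.data.shape[0] < 3:
        raise ValueError("need at least 3 genomes for rank correlations")
    x = matrix.data.to_numpy(dtype=float)
    m = x.shape[1]
    constant = np.ptp(x, axis=0) == 0
    rho = np.full((m, m), np.nan)
    keep = np.flatnonzero(~constant)
    if len(keep) == 1:
        rho[keep[0], keep[0]] = 1.0
    elif len(keep) >= 2:
        sub = spearmanr(x[:, keep]).statistic
        if np.ndim(sub) == 0:  # scipy returns a scalar for exactly 2 variables
            sub = np.array([[1.0, float(sub)], [float(sub), 1.0]])
        rho[np.ix_(keep, keep)] = sub
    return pd.DataFrame(rho, index=matrix.data.columns, columns=matrix.data.columns)


def dendrogram_to_newick(linkage: np.ndarray, ids: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with genome-id leaves."""
    tree = sch.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return ids[node.id].replace(" ", "_")
        left = render(node.get_left())
        right = render(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return render(tree) + ";"
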
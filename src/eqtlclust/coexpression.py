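"""Coexpression scoring and group comparisons.

The coexpression of a gene group is the mean over all gene pairs of the
absolute Pearson correlation of strain-level expression.  Group
comparisons follow the field's standard recipe: Student's t-test for
two groups, one-way ANOVA followed by Tukey's HSD for more.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import ExpressionMatrix, GeneAnnotation, HaplotypeBlock

__all__ = [
    "cluster_coexpression",
    "random_gene_groups",
    "compare_coexpression",
    "block_coexpression",
    "CoexpressionResult",
    "null_abs_r_expectation",
]


def _pairwise_abs_r(mat: np.ndarray) -> list[float]:
    """|Pearson r| for each row pair, pairwise-complete over columns;
    pairs with zero variance in either row are skipped with a warning."""
    if not np.isnan(mat).any() and (mat.std(axis=1) > 0).all():
        r = np.corrcoef(mat)
        iu = np.triu_indices(mat.shape[0], k=1)
        return np.abs(r[iu]).tolist()
    vals = []
    skipped = 0
    for i, j in itertools.combinations(range(mat.shape[0]), 2):
        ok = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
        if ok.sum() < 3:
            skipped += 1
            continue
        a, b = mat[i, ok], mat[j, ok]
        if a.std() == 0 or b.std() == 0:
            skipped += 1
            continue
        vals.append(abs(float(np.corrcoef(a, b)[0, 1])))
    if skipped:
        warnings.warn(
            f"skipped {skipped} gene pair(s) with zero variance or <3 shared strains",
            stacklevel=3,
        )
    return vals


def cluster_coexpression(gene_ids, expr: ExpressionMatrix) -> float:
    """Mean pairwise |Pearson r| among the given genes across strains."""
    gene_ids = [g for g in gene_ids if g in expr.values.index]
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes with expression rows")
    mat = expr.values.loc[gene_ids].to_numpy(dtype=float)
    vals = _pairwise_abs_r(mat)
    if not vals:
        raise ValueError("no usable gene pairs (all zero-variance)")
    return float(np.mean(vals))


def random_gene_groups(
    universe: list[str],
    size_range: tuple[int, int],
    n_groups: int,
    expr: ExpressionMatrix,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[float], list[tuple[str, ...]]]:
    """Coexpression of random gene sets drawn genome-wide.

    Each group's size is uniform over ``size_range`` (inclusive) and its
    genes are sampled without replacement from the universe, ignoring
    genomic position entirely.  Returns (per-group mean |r|, group
    compositions); deterministic for a given generator state.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("group size range exceeds the gene universe")
    universe = list(universe)
    values, groups = [], []
    for _ in range(n_groups):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(universe, size=size, replace=False))
        groups.append(members)
        values.append(cluster_coexpression(list(members), expr))
    return values, groups


@dataclass
class CoexpressionResult:
    """Per-group summaries plus pairwise test p-values."""

    values: dict[str, list[float]]
    means: dict[str, float]
    sds: dict[str, float]
    anova_p: float | None
    pairwise_p: pd.DataFrame = field(default_factory=pd.DataFrame)
    """columns: group1, group2, p (t-test for 2 groups, Tukey HSD otherwise)"""

    def p_between(self, a: str, b: str) -> float:
        for row in self.pairwise_p.itertuples():
            if {row.group1, row.group2} == {a, b}:
                return float(row.p)
        raise KeyError(f"no comparison between {a!r} and {b!r}")


def compare_coexpression(groups: dict[str, list[float]]) -> CoexpressionResult:
    """Compare labelled per-cluster coexpression value lists.

    Two groups: two-sample t-test.  More: one-way ANOVA, then Tukey HSD
    for all pairwise contrasts.
    """
    labels = [k for k, v in groups.items() if len(v) >= 2]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    data = {k: np.asarray(groups[k], dtype=float) for k in labels}
    if all(v.std() == 0 for v in data.values()):
        raise ValueError("zero within-group variance in every group")
    means = {k: float(v.mean()) for k, v in data.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in data.items()}
    if len(labels) == 2:
        a, b = labels
        t = stats.ttest_ind(data[a], data[b])
        pw = pd.DataFrame([{"group1": a, "group2": b, "p": float(t.pvalue)}])
        return CoexpressionResult(groups, means, sds, None, pw)
    anova = stats.f_oneway(*(data[k] for k in labels))
    anova_p = float(anova.pvalue)
    if np.isnan(anova_p) and abs(float(anova.statistic)) < 1e-9:
        anova_p = 1.0  # identical group means, numerically negative-zero F
    flat = np.concatenate([data[k] for k in labels])
    labs = np.concatenate([[k] * len(data[k]) for k in labels])
    tukey = pairwise_tukeyhsd(flat, labs)
    pw = pd.DataFrame(
        tukey.summary().data[1:], columns=[c.strip() for c in tukey.summary().data[0]]
    )[["group1", "group2", "p-adj"]].rename(columns={"p-adj": "p"})
    pw["p"] = pw["p"].astype(float)
    return CoexpressionResult(groups, means, sds, anova_p, pw)


def block_coexpression(
    blocks: list[HaplotypeBlock],
    annotation: GeneAnnotation,
    expr: ExpressionMatrix,
) -> pd.DataFrame:
    """Coexpression of the detected genes inside each minimal haplotype
    block (gene start within the half-open block span); blocks with
    fewer than 2 such genes are skipped.
    """
    ann = annotation.df
    detected = ann.loc[ann.index.intersection(expr.values.index)]
    rows = []
    for blk in blocks:
        inside = detected[
            (detected["chrom"] == blk.chrom)
            & (detected["start"] >= blk.start)
            & (detected["start"] < blk.end)
        ]
        if len(inside) < 2:
            continue
        try:
            value = cluster_coexpression(inside.index.tolist(), expr)
        except ValueError:
            continue
        rows.append(
            {
                "chrom": blk.chrom,
                "start": blk.start,
                "end": blk.end,
                "n_genes": len(inside),
                "mean_abs_r": value,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_genes", "mean_abs_r"])


def null_abs_r_expectation(n: int) -> float:
    """E|r| for the Pearson correlation of two independent normal
    vectors of length n.  Under the null, r^2 ~ Beta(1/2, (n-2)/2), so
    E|r| = B(1, (n-2)/2) / B(1/2, (n-2)/2).
    """
    from scipy.special import beta as beta_fn

    return float(beta_fn(1.0, (n - 2) / 2.0) / beta_fn(0.5, (n - 2) / 2.0))
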
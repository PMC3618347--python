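"""Max-gap interval clustering of cis-eQTL genes and the matched
null region sets (control clusters, random boxes, single-eQTL regions,
minimal haplotype blocks).

A cis-eQTL cluster is a maximal run of cis-eQTL gene starts on one
chromosome in which consecutive starts are separated by at most the
window size (250/500/750 kb), with at least ``min_cluster_size``
members.  The cluster span runs from the first to the last member gene
start; gene ends are never used.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    Cluster,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicRegion,
    GenotypeMatrix,
    HaplotypeBlock,
)

__all__ = [
    "detect_clusters",
    "build_control_clusters",
    "sample_random_regions",
    "augment_flanks",
    "single_eqtl_regions",
    "haplotype_blocks",
    "adjacent_marker_ld",
    "cluster_heterogeneity",
    "clusters_to_frame",
]

logger = logging.getLogger(__name__)


def _as_position_frame(genes: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene_id", "chrom", "start"):
        if col not in genes.columns:
            raise ValueError(f"gene position table missing column {col!r}")
    df = genes.drop_duplicates(subset="gene_id")
    return df.sort_values(["chrom", "start"], kind="stable")


def detect_clusters(
    genes: pd.DataFrame,
    max_gap_bp: int,
    min_cluster_size: int = 3,
    kind: str = "cis",
) -> list[Cluster]:
    """Greedy left-to-right max-gap merge of gene starts per chromosome.

    ``genes``: columns gene_id, chrom, start.  A gene joins the open
    cluster iff its start minus the previous member's start is at most
    ``max_gap_bp``; runs shorter than ``min_cluster_size`` are dropped.
    The result is the unique maximal partition: output is invariant to
    input order and idempotent.
    """
    df = _as_position_frame(genes)
    clusters: list[Cluster] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        run_start = 0
        for i in range(1, len(starts) + 1):
            if i == len(starts) or starts[i] - starts[i - 1] > max_gap_bp:
                if i - run_start >= min_cluster_size:
                    members = tuple(ids[run_start:i])
                    lo, hi = int(starts[run_start]), int(starts[i - 1])
                    clusters.append(
                        Cluster(
                            kind=kind,
                            chrom=str(chrom),
                            span=GenomicRegion(str(chrom), lo, max(hi, lo + 1)),
                            members=members,
                            window_bp=max_gap_bp,
                        )
                    )
                run_start = i
    return clusters


def build_control_clusters(
    detected_genes: pd.DataFrame,
    cis_clusters: list[Cluster],
    max_gap_bp: int,
    min_cluster_size: int = 3,
    max_span_bp: int | None = None,
) -> tuple[list[Cluster], dict]:
    """Size-matched control clusters from ALL detected genes.

    The same max-gap merge is applied to every gene detected on the
    platform (not only cis-eQTL genes); candidates whose span exceeds
    ``max_span_bp`` (default: the largest cis-cluster span for the same
    window) or which overlap any cis-cluster span are dropped.  Returns
    the controls plus a matching report: two-sample t-tests of span and
    member count against the cis clusters (a good match has p > 0.05 on
    both).
    """
    if max_span_bp is None:
        max_span_bp = max((c.span_bp for c in cis_clusters), default=None)
    candidates = detect_clusters(
        detected_genes, max_gap_bp, min_cluster_size, kind="control"
    )
    cis_spans = [c.span for c in cis_clusters]
    controls = [
        c
        for c in candidates
        if (max_span_bp is None or c.span_bp <= max_span_bp)
        and not any(c.span.overlaps(s) for s in cis_spans)
    ]
    report: dict = {
        "n_cis": len(cis_clusters),
        "n_control": len(controls),
        "max_span_bp": max_span_bp,
        "span_p": np.nan,
        "size_p": np.nan,
    }
    if len(controls) >= 2 and len(cis_clusters) >= 2:
        span_p = stats.ttest_ind(
            [c.span_bp for c in controls], [c.span_bp for c in cis_clusters]
        ).pvalue
        size_p = stats.ttest_ind(
            [c.n_members for c in controls], [c.n_members for c in cis_clusters]
        ).pvalue
        report["span_p"], report["size_p"] = float(span_p), float(size_p)
        if span_p < 0.05 or size_p < 0.05:
            warnings.warn(
                "control clusters differ from cis clusters "
                f"(span p={span_p:.3g}, size p={size_p:.3g})",
                stacklevel=2,
            )
    return controls, report


def sample_random_regions(
    chrom_sizes: dict[str, int],
    size_list: list[int],
    n_per_size: int,
    exclusions: list[GenomicRegion] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Cluster]:
    """Random genomic boxes, uniform over the genome.

    For each requested size, the chromosome is drawn with probability
    proportional to (length - size) and the start uniformly; draws
    overlapping an exclusion region are rejected and resampled.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    exclusions = exclusions or []
    out: list[Cluster] = []
    attempts = 0
    accepted = 0
    for size in size_list:
        size = int(size)
        chroms = [c for c, length in chrom_sizes.items() if length >= size]
        if not chroms:
            raise ValueError(f"region size {size} exceeds every chromosome")
        weights = np.array([chrom_sizes[c] - size for c in chroms], dtype=float)
        if weights.sum() == 0:
            weights[:] = 1.0
        weights /= weights.sum()
        for _ in range(n_per_size):
            while True:
                attempts += 1
                if attempts > 100 * (accepted + 1) and attempts > 1000:
                    raise RuntimeError(
                        "random-region rejection rate above 99%: exclusions "
                        "cover too much of the genome"
                    )
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                start = int(rng.integers(0, chrom_sizes[chrom] - size + 1))
                region = GenomicRegion(chrom, start, start + size)
                if not any(region.overlaps(e) for e in exclusions):
                    accepted += 1
                    out.append(Cluster(kind="random", chrom=chrom, span=region))
                    break
    return out


def augment_flanks(
    region: GenomicRegion, flank_bp: int, chrom_length: int
) -> GenomicRegion:
    """Grow a region by ``flank_bp`` on both sides, clipped to the
    chromosome: [max(0, start-flank), min(length, end+flank))."""
    return GenomicRegion(
        region.chrom,
        max(0, region.start - flank_bp),
        min(chrom_length, region.end + flank_bp),
        region.label,
    )


def single_eqtl_regions(
    singletons: pd.DataFrame,
    size_bp: int,
    chrom_sizes: dict[str, int],
) -> list[Cluster]:
    """Boxes of ``size_bp`` centered on each single (unclustered)
    cis-eQTL gene start, clipped at chromosome edges.

    ``singletons``: columns gene_id, chrom, start.
    """
    out = []
    half = size_bp // 2
    for row in _as_position_frame(singletons).itertuples():
        length = chrom_sizes[row.chrom]
        lo = max(0, int(row.start) - half)
        hi = min(length, int(row.start) + (size_bp - half))
        out.append(
            Cluster(
                kind="single",
                chrom=row.chrom,
                span=GenomicRegion(row.chrom, lo, hi, label=row.gene_id),
                members=(row.gene_id,),
            )
        )
    return out


def haplotype_blocks(geno: GenotypeMatrix) -> list[HaplotypeBlock]:
    """Minimal haplotype blocks: one per consecutive pair of informative
    markers on a chromosome; no informative marker lies in an interior."""
    blocks = []
    by_chrom: dict[str, list] = {}
    for m in geno.informative():
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, ms in sorted(by_chrom.items()):
        if len(ms) < 2:
            warnings.warn(
                f"chromosome {chrom} has <2 informative markers; no blocks",
                stacklevel=2,
            )
            continue
        for a, b in zip(ms, ms[1:]):
            blocks.append(
                HaplotypeBlock(
                    chrom=chrom,
                    start=a.pos,
                    end=b.pos,
                    left_marker=a.id,
                    right_marker=b.id,
                )
            )
    return blocks


def adjacent_marker_ld(geno: GenotypeMatrix) -> pd.DataFrame:
    """r^2 between each pair of adjacent informative markers on the same
    chromosome: squared Pearson correlation of the 0/1 allele codes over
    strains complete for the pair.  Pairs monomorphic after missing
    removal get NaN.
    """
    rows = []
    informative = geno.informative()
    for a, b in zip(informative, informative[1:]):
        if a.chrom != b.chrom:
            continue
        x, y = geno.column(a.id), geno.column(b.id)
        ok = ~np.isnan(x) & ~np.isnan(y)
        r2 = np.nan
        if ok.sum() >= 3:
            xs, ys = x[ok], y[ok]
            if xs.std() > 0 and ys.std() > 0:
                r = np.corrcoef(xs, ys)[0, 1]
                r2 = float(r * r)
        rows.append(
            {
                "chrom": a.chrom,
                "marker_a": a.id,
                "marker_b": b.id,
                "pos_a": a.pos,
                "pos_b": b.pos,
                "r2": r2,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "marker_a", "marker_b", "pos_a", "pos_b", "r2"])


def cluster_heterogeneity(
    cluster: Cluster,
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
) -> tuple[bool, bool | None]:
    """Regulation-direction and strand heterogeneity of a cluster.

    direction_consistent: all pairwise Pearson correlations among member
    expression profiles are positive (every member moves the same way
    with the allele).  both_strands: members include both + and -
    strands; None when any member lacks strand annotation.
    """
    members = [g for g in cluster.members if g in expr.values.index]
    if len(members) < 2:
        raise ValueError("cluster has <2 members with expression")
    mat = expr.values.loc[members].to_numpy(dtype=float)
    r = np.corrcoef(mat)
    iu = np.triu_indices(len(members), k=1)
    direction_consistent = bool((r[iu] > 0).all())
    strands = set()
    for g in cluster.members:
        if g not in annotation:
            return direction_consistent, None
        s = annotation.strand(g)
        if s not in ("+", "-"):
            return direction_consistent, None
        strands.add(s)
    return direction_consistent, strands == {"+", "-"}


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Flat TSV-ready table of any cluster list."""
    return pd.DataFrame(
        [
            {
                "kind": c.kind,
                "chrom": c.chrom,
                "span_start": c.span.start,
                "span_end": c.span.end,
                "n_members": c.n_members,
                "members": ";".join(c.members),
                "window_bp": c.window_bp if c.window_bp is not None else "",
            }
            for c in clusters
        ],
        columns=[
            "kind",
            "chrom",
            "span_start",
            "span_end",
            "n_members",
            "members",
            "window_bp",
        ],
    )
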
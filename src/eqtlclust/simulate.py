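"""Synthetic recombinant-inbred panel generator.

Emulates the study design every downstream stage expects: an inbred
panel whose chromosomes are mosaics of two parental genomes, strain-
level expression with planted clusters of neighboring, coexpressed,
allele-driven genes, and interval feature tracks (e.g. polymorphic
SINE catalogs) with elevated density inside the planted regions.

The generative model for a gene *g* in planted cluster *c* with driving
marker *m*::

    y(g, s) = mu_g + s_g * beta * x(m, s) + s_g * rho_latent * F(c, s) + eps

where ``x`` is the 0/1 parental allele of strain *s*, ``F(c, .)`` is a
standard-normal latent factor shared by the cluster's genes (a shared
regulatory influence beyond the marker itself), ``s_g`` a per-gene
random sign — so member genes are strongly coexpressed in magnitude but
not uniformly up- or down-regulated — and ``eps ~ N(0, sigma^2)``.
Background genes are pure noise around their baseline.

Theoretical within-cluster pairwise correlation magnitude is

    |r| = (beta^2/4 + rho_latent^2) / (beta^2/4 + rho_latent^2 + sigma^2)

The defaults (beta=3.2, rho_latent=sqrt(0.44), sigma=1) set this to
0.75 — the coexpression level the method is designed to detect — while
keeping each member gene individually mappable at LOD >= 3.3 with 24
strains (genotype share of variance 0.64).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .types import (
    ExpressionMatrix,
    FeatureTrack,
    GeneAnnotation,
    GenomicRegion,
    GenotypeMatrix,
    Marker,
)

__all__ = [
    "SimConfig",
    "PlantedCluster",
    "SimTruth",
    "SimBundle",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_expression",
    "simulate_feature_track",
    "simulate_bundle",
    "write_bundle",
    "read_truth",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    The genome is a scaled-down stand-in: n_chrom chromosomes of
    chrom_length_bp with n_markers evenly spaced markers genome-wide.
    beta is the allelic effect and sigma the residual SD, both on the
    log2-expression scale; rho_latent the within-cluster latent-factor
    loading.
    """

    n_strains: int = 24
    n_chrom: int = 5
    chrom_length_bp: int = 100_000_000
    n_markers: int = 1000
    marker_switch_prob: float = 0.10
    n_genes: int = 2000
    n_planted_clusters: int = 10
    genes_per_cluster: int = 4
    cluster_span_bp: int = 250_000
    beta: float = 3.2
    rho_latent: float = math.sqrt(0.44)
    sigma: float = 1.0
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    n_replicates: int = 4
    detect_prob: float = 0.95
    undetected_gene_fraction: float = 0.05
    undetected_detect_prob: float = 0.2
    feature_rate_in: float = 12.0  # features per Mb inside planted spans (+flank)
    feature_rate_out: float = 4.0
    feature_flank_bp: int = 250_000
    feature_length_bp: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.marker_switch_prob < 0.5:
            raise ValueError("marker_switch_prob must be in [0, 0.5)")
        if self.feature_rate_in < self.feature_rate_out or self.feature_rate_out < 0:
            raise ValueError("need feature_rate_in >= feature_rate_out >= 0")
        if self.genes_per_cluster < 2:
            raise ValueError("genes_per_cluster must be >= 2")
        if self.n_planted_clusters * self.genes_per_cluster > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}

    def expected_within_cluster_abs_r(self) -> float:
        shared = self.beta**2 / 4 + self.rho_latent**2
        return shared / (shared + self.sigma**2)


@dataclass(frozen=True)
class PlantedCluster:
    chrom: str
    gene_ids: tuple[str, ...]
    span: GenomicRegion
    marker_id: str
    beta: float
    rho_latent: float


@dataclass
class SimTruth:
    """Ground truth of one simulated bundle."""

    planted_clusters: list[PlantedCluster]
    feature_rates: dict[str, tuple[float, float]]  # track -> (rate_in, rate_out)
    seed: int

    def member_sets(self) -> list[set[str]]:
        return [set(c.gene_ids) for c in self.planted_clusters]


@dataclass
class SimBundle:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    tracks: dict[str, FeatureTrack]
    chrom_sizes: dict[str, int]
    truth: SimTruth


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(cfg: SimConfig, seed) -> GenotypeMatrix:
    """Two-state Markov mosaic per strain chromosome.

    The first marker on each chromosome is Bernoulli(1/2); each
    subsequent marker flips parental state with probability
    marker_switch_prob.  All calls are homozygous (A or B).  Markers sit
    on an even grid, ``n_markers / n_chrom`` per chromosome.
    """
    rng = _rng(seed)
    per_chrom = cfg.n_markers // cfg.n_chrom
    if per_chrom < 2:
        raise ValueError("need at least 2 markers per chromosome")
    markers: list[Marker] = []
    blocks: list[np.ndarray] = []
    spacing = cfg.chrom_length_bp / per_chrom
    for chrom in cfg.chrom_names:
        pos = ((np.arange(per_chrom) + 0.5) * spacing).astype(int)
        markers.extend(
            Marker(f"{chrom}_m{j + 1:04d}", chrom, int(p)) for j, p in enumerate(pos)
        )
        calls = np.empty((cfg.n_strains, per_chrom), dtype=float)
        calls[:, 0] = rng.random(cfg.n_strains) < 0.5
        flips = rng.random((cfg.n_strains, per_chrom - 1)) < cfg.marker_switch_prob
        for j in range(1, per_chrom):
            calls[:, j] = np.logical_xor(calls[:, j - 1], flips[:, j - 1])
        blocks.append(calls)
    strains = [f"RIS{i + 1:02d}" for i in range(cfg.n_strains)]
    return GenotypeMatrix(strains, markers, np.concatenate(blocks, axis=1))


def _plant_clusters(
    cfg: SimConfig, geno: GenotypeMatrix, rng: np.random.Generator
) -> list[tuple[str, int, int, str]]:
    """Choose non-overlapping planted spans, each centered on an
    informative driving marker (so the locus lies inside the span)."""
    informative = [
        m
        for m in geno.informative()
        if cfg.cluster_span_bp // 2 <= m.pos <= cfg.chrom_length_bp - cfg.cluster_span_bp // 2
    ]
    if len(informative) < cfg.n_planted_clusters:
        raise ValueError("not enough informative markers to plant clusters")
    chosen: list[tuple[str, int, int, str]] = []
    order = rng.permutation(len(informative))
    half = cfg.cluster_span_bp // 2
    for idx in order:
        m = informative[idx]
        lo, hi = m.pos - half, m.pos + half
        if any(c == m.chrom and lo < h and l < hi for c, l, h, _ in chosen):
            continue
        chosen.append((m.chrom, lo, hi, m.id))
        if len(chosen) == cfg.n_planted_clusters:
            break
    else:
        raise ValueError("could not place non-overlapping planted clusters")
    return chosen


def simulate_annotation(
    cfg: SimConfig, geno: GenotypeMatrix, seed
) -> tuple[GeneAnnotation, SimTruth]:
    """Place gene starts and define the planted clusters.

    Cluster members are consecutive genes inside each planted span
    (background genes are kept out of the spans); all other gene starts
    are uniform over the genome.  Gene ids are assigned in (chrom, pos)
    order.
    """
    rng = _rng(seed)
    spans = _plant_clusters(cfg, geno, rng)
    records: list[tuple[str, int, int]] = []  # chrom, pos, cluster index
    for k, (chrom, lo, hi, _marker) in enumerate(spans):
        pos = np.sort(rng.integers(lo, hi, cfg.genes_per_cluster))
        while len(set(pos.tolist())) < len(pos):  # distinct starts
            pos = np.sort(rng.integers(lo, hi, cfg.genes_per_cluster))
        records.extend((chrom, int(p), k) for p in pos)
    n_background = cfg.n_genes - cfg.n_planted_clusters * cfg.genes_per_cluster
    placed = 0
    while placed < n_background:
        chrom = cfg.chrom_names[rng.integers(cfg.n_chrom)]
        p = int(rng.integers(0, cfg.chrom_length_bp))
        if any(c == chrom and lo <= p < hi for c, lo, hi, _ in spans):
            continue
        records.append((chrom, p, -1))
        placed += 1
    records.sort(key=lambda t: (t[0], t[1]))
    gene_ids = [f"G{i + 1:05d}" for i in range(len(records))]
    strands = rng.choice(["+", "-"], size=len(records))
    df = pd.DataFrame(
        {
            "chrom": [r[0] for r in records],
            "start": [r[1] for r in records],
            "strand": strands,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    members: dict[int, list[str]] = {k: [] for k in range(len(spans))}
    for gid, (_, _, k) in zip(gene_ids, records):
        if k >= 0:
            members[k].append(gid)
    planted = [
        PlantedCluster(
            chrom=spans[k][0],
            gene_ids=tuple(members[k]),
            span=GenomicRegion(spans[k][0], spans[k][1], spans[k][2]),
            marker_id=spans[k][3],
            beta=cfg.beta,
            rho_latent=cfg.rho_latent,
        )
        for k in range(len(spans))
    ]
    truth = SimTruth(
        planted_clusters=planted,
        feature_rates={},
        seed=seed if isinstance(seed, int) else -1,
    )
    return GeneAnnotation(df), truth


def simulate_expression(
    geno: GenotypeMatrix,
    annotation: GeneAnnotation,
    truth: SimTruth,
    cfg: SimConfig,
    seed,
) -> ExpressionMatrix:
    """Strain-level expression plus a replicate-level detection layer."""
    rng = _rng(seed)
    genes = annotation.df.index.tolist()
    n, s = len(genes), geno.n_strains
    gene_row = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    values = baseline[:, None] + rng.normal(0.0, cfg.sigma, size=(n, s))
    signs = rng.choice([-1.0, 1.0], size=n)
    planted_rows: set[int] = set()
    for cluster in truth.planted_clusters:
        x = geno.column(cluster.marker_id)
        if np.isnan(x).any():
            raise ValueError("driving marker has missing calls")
        factor = rng.standard_normal(s)
        for g in cluster.gene_ids:
            if g not in gene_row:
                raise ValueError(f"planted gene {g!r} not in annotation")
            i = gene_row[g]
            planted_rows.add(i)
            values[i] += signs[i] * (cluster.beta * x + cluster.rho_latent * factor)
    # detection layer: most genes detected in nearly all replicates;
    # a small fraction (never planted) mimics undetected transcripts
    # and exercises the >50%-of-replicates filter.
    p_detect = np.full(n, cfg.detect_prob)
    n_undetected = int(round(cfg.undetected_gene_fraction * n))
    candidates = np.array([i for i in range(n) if i not in planted_rows])
    if n_undetected and candidates.size:
        low = rng.choice(candidates, size=min(n_undetected, candidates.size), replace=False)
        p_detect[low] = cfg.undetected_detect_prob
    det = rng.random((n, s * cfg.n_replicates)) < p_detect[:, None]
    columns = pd.MultiIndex.from_tuples(
        [(st, f"r{k + 1}") for st in geno.strains for k in range(cfg.n_replicates)],
        names=["strain", "replicate"],
    )
    detection = pd.DataFrame(det, index=pd.Index(genes, name="gene_id"), columns=columns)
    vdf = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=geno.strains)
    return ExpressionMatrix(vdf, detection)


def simulate_feature_track(
    truth: SimTruth,
    chrom_sizes: dict[str, int],
    cfg: SimConfig,
    seed,
    name: str = "sine_polymorphic",
    rate_in: float | None = None,
    rate_out: float | None = None,
    class_label: str = "SINE",
    status: str = "polymorphic",
) -> FeatureTrack:
    """Piecewise-homogeneous Poisson feature track.

    Feature starts arrive at ``rate_in`` per Mb inside planted spans
    (grown by feature_flank_bp on both sides) and ``rate_out`` per Mb
    elsewhere; every feature is feature_length_bp long.
    """
    rng = _rng(seed)
    rate_in = cfg.feature_rate_in if rate_in is None else rate_in
    rate_out = cfg.feature_rate_out if rate_out is None else rate_out
    if rate_in < rate_out:
        raise ValueError("rate_in must be >= rate_out")
    inside: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for cluster in truth.planted_clusters:
        lo = max(0, cluster.span.start - cfg.feature_flank_bp)
        hi = min(chrom_sizes[cluster.chrom], cluster.span.end + cfg.feature_flank_bp)
        inside[cluster.chrom].append((lo, hi))
    rows: list[tuple[str, int, int]] = []

    def emit(chrom: str, lo: int, hi: int, rate: float) -> None:
        length_mb = (hi - lo) / 1e6
        count = rng.poisson(rate * length_mb)
        if count:
            starts = np.sort(rng.integers(lo, hi, count))
            rows.extend((chrom, int(st), int(st) + cfg.feature_length_bp) for st in starts)

    for chrom, size in chrom_sizes.items():
        # merge overlapping inside intervals so no segment is emitted twice
        segs: list[tuple[int, int]] = []
        for lo, hi in sorted(inside[chrom]):
            if segs and lo <= segs[-1][1]:
                segs[-1] = (segs[-1][0], max(segs[-1][1], hi))
            else:
                segs.append((lo, hi))
        cursor = 0
        for lo, hi in segs:
            if lo > cursor:
                emit(chrom, cursor, lo, rate_out)
            emit(chrom, lo, hi, rate_in)
            cursor = hi
        if cursor < size:
            emit(chrom, cursor, size, rate_out)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["label"] = [f"{name}_{i + 1}" for i in range(len(df))]
    df["class_label"] = class_label
    df["status"] = status
    df["orientation"] = "n/a"
    truth.feature_rates[name] = (rate_in, rate_out)
    return FeatureTrack(name, df)


def simulate_bundle(cfg: SimConfig | None = None, seed: int = 0) -> SimBundle:
    """Generate a full input bundle: genotypes, annotation, expression,
    one enriched and one homogeneous feature track, and the truth record.

    All stages draw from child generators spawned deterministically from
    ``seed``, so the bundle is a pure function of (cfg, seed).
    """
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(seed)
    s_geno, s_annot, s_expr, s_trk1, s_trk2 = root.spawn(5)
    geno = simulate_genotypes(cfg, np.random.default_rng(s_geno))
    annotation, truth = simulate_annotation(cfg, geno, np.random.default_rng(s_annot))
    truth.seed = seed
    expr = simulate_expression(geno, annotation, truth, cfg, np.random.default_rng(s_expr))
    tracks = {
        "sine_polymorphic": simulate_feature_track(
            truth,
            cfg.chrom_sizes,
            cfg,
            np.random.default_rng(s_trk1),
            name="sine_polymorphic",
            class_label="SINE",
            status="polymorphic",
        ),
        "sine_fixed": simulate_feature_track(
            truth,
            cfg.chrom_sizes,
            cfg,
            np.random.default_rng(s_trk2),
            name="sine_fixed",
            rate_in=cfg.feature_rate_out,
            rate_out=cfg.feature_rate_out,
            class_label="SINE",
            status="fixed",
        ),
    }
    return SimBundle(geno, expr, annotation, tracks, cfg.chrom_sizes, truth)


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as the pipeline's input file set; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "expression": out / "expression.tsv",
        "detection": out / "detection.tsv",
        "annotation": out / "annotation.tsv",
        "chrom_sizes": out / "chrom.sizes",
        "truth": out / "truth.json",
    }
    eio.write_genotypes(bundle.genotypes, paths["genotypes"])
    eio.write_expression(bundle.expression, paths["expression"], paths["detection"])
    eio.write_annotation(bundle.annotation, paths["annotation"])
    eio.write_chrom_sizes(bundle.chrom_sizes, paths["chrom_sizes"])
    for name, track in bundle.tracks.items():
        p = out / f"track_{name}.bed"
        eio.write_features_bed(track, p)
        paths[f"track_{name}"] = p
    truth_obj = {
        "seed": bundle.truth.seed,
        "feature_rates": bundle.truth.feature_rates,
        "planted_clusters": [
            {
                "chrom": c.chrom,
                "gene_ids": list(c.gene_ids),
                "start": c.span.start,
                "end": c.span.end,
                "marker_id": c.marker_id,
                "beta": c.beta,
                "rho_latent": c.rho_latent,
            }
            for c in bundle.truth.planted_clusters
        ],
    }
    paths["truth"].write_text(json.dumps(truth_obj, indent=1))
    return paths


def read_truth(path: str | Path) -> SimTruth:
    obj = json.loads(Path(path).read_text())
    planted = [
        PlantedCluster(
            chrom=c["chrom"],
            gene_ids=tuple(c["gene_ids"]),
            span=GenomicRegion(c["chrom"], c["start"], c["end"]),
            marker_id=c["marker_id"],
            beta=c["beta"],
            rho_latent=c["rho_latent"],
        )
        for c in obj["planted_clusters"]
    ]
    rates = {k: tuple(v) for k, v in obj["feature_rates"].items()}
    return SimTruth(planted, rates, obj["seed"])
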
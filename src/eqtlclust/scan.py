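"""Single-marker eQTL scans.

For each transcript, expression across strains is regressed on the
parental-allele code at every marker; the evidence at a marker is the
LOD score

    LOD = (n/2) * log10(RSS0 / RSS1)

with RSS0 the residual sum of squares about the grand mean and RSS1
from the one-way genotype-group-mean fit, over the n strains with
complete data at that marker.  For a biallelic marker this equals
-(n/2) * log10(1 - r^2) with r the Pearson correlation between
expression and allele code.  A transcript is an eQTL when its peak LOD
reaches the genome-wide threshold (default 3.3), and a cis-eQTL when
the peak marker lies within the cis window (default 1 Mb) of the gene's
transcription start on the same chromosome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .types import (
    EqtlRecord,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicRegion,
    GenotypeMatrix,
    LodScan,
    ProbeSnpFlag,
)

__all__ = [
    "filter_detected_genes",
    "lod_scan",
    "scan_all",
    "call_eqtls",
    "eqtls_to_frame",
    "flag_probe_snps",
]

logger = logging.getLogger(__name__)

#: LOD value reported for a perfect (zero-residual) fit.  Far above any
#: threshold in use; keeps the arithmetic finite.
LOD_CAP = 50.0


def filter_detected_genes(
    expr: ExpressionMatrix, detection_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep genes detected in strictly more than ``detection_fraction``
    of the replicates for at least one strain.

    A gene detected in exactly half the replicates of every strain is
    dropped (the comparison is strict).
    """
    if expr.detection is None:
        raise ValueError("expression matrix has no detection layer")
    frac = expr.detection.T.groupby(level="strain").mean().T  # gene x strain
    keep = (frac > detection_fraction).any(axis=1)
    kept = expr.values.index[keep].tolist()
    logger.info("detection filter kept %d / %d genes", len(kept), expr.n_genes)
    return expr.subset_genes(kept)


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """LOD from the two residual sums of squares, with the perfect-fit cap."""
    lod = np.zeros_like(rss0, dtype=float)
    ok = (rss0 > 0) & (n >= 3)
    floor = rss0 * np.power(10.0, -2.0 * LOD_CAP / np.maximum(n, 1))
    capped = ok & (rss1 <= floor)
    normal = ok & ~capped
    with np.errstate(divide="ignore", invalid="ignore"):
        lod[normal] = (n[normal] / 2.0) * np.log10(rss0[normal] / rss1[normal])
    lod[capped] = LOD_CAP
    return np.clip(lod, 0.0, LOD_CAP)


def _marker_lods(values: np.ndarray, present: np.ndarray, x: np.ndarray):
    """LOD of every gene at one marker.

    values: gene x strain expression (NaN for missing),
    present: boolean validity of values, x: 0/1/NaN allele codes.
    Returns (lods, n) arrays over genes.
    """
    v = ~np.isnan(x)
    xv = x[v]
    m = present[:, v]
    yv = np.where(m, values[:, v], 0.0)
    n = m.sum(axis=1)
    n1 = m @ xv
    n0 = n - n1
    s = yv.sum(axis=1)
    s1 = yv @ xv
    s0 = s - s1
    ss = (yv**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = ss - np.where(n > 0, s**2 / np.maximum(n, 1), 0.0)
        between = np.where(n1 > 0, s1**2 / np.maximum(n1, 1), 0.0) + np.where(
            n0 > 0, s0**2 / np.maximum(n0, 1), 0.0
        )
        rss1 = ss - between
    rss0 = np.maximum(rss0, 0.0)
    rss1 = np.maximum(rss1, 0.0)
    lods = _lod_from_rss(rss0, rss1, n)
    lods[(n1 == 0) | (n0 == 0)] = 0.0  # one genotype class only
    return lods, n


def _all_marker_lods_complete(values: np.ndarray, calls: np.ndarray) -> np.ndarray:
    """Vectorized complete-data path: LOD for every (gene, marker) via
    the one-way group-sum decomposition (same arithmetic as the
    per-marker path, computed as one matrix product)."""
    n = values.shape[1]
    n1 = calls.sum(axis=0)  # per marker
    n0 = n - n1
    s = values.sum(axis=1, keepdims=True)  # per gene
    ss = (values**2).sum(axis=1, keepdims=True)
    s1 = values @ calls  # gene x marker sums in genotype class B
    s0 = s - s1
    rss0 = np.maximum(ss - s**2 / n, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        between = np.where(n1 > 0, s1**2 / np.maximum(n1, 1), 0.0) + np.where(
            n0 > 0, s0**2 / np.maximum(n0, 1), 0.0
        )
    rss1 = np.maximum(ss - between, 0.0)
    n_arr = np.full(rss1.shape, float(n))
    lods = _lod_from_rss(np.broadcast_to(rss0, rss1.shape).copy(), rss1, n_arr)
    lods[:, (n1 == 0) | (n0 == 0)] = 0.0
    return lods


def scan_all(expr: ExpressionMatrix, geno: GenotypeMatrix) -> list[LodScan]:
    """LOD scans for every gene in the expression matrix.

    Strains are aligned by id; expression strains absent from the
    genotypes are a hard error.  Per (gene, marker), strains missing
    either value are dropped (complete-case).  Genes with fewer than 3
    complete strains at every marker are a hard error.
    """
    missing = [s for s in expr.strains if s not in geno.strains]
    if missing:
        raise ValueError(f"strains missing from genotypes: {missing}")
    geno = geno.subset_strains(expr.strains)
    values = expr.values.to_numpy(dtype=float)
    present = ~np.isnan(values)
    n_genes, n_markers = values.shape[0], geno.n_markers
    if present.all() and not np.isnan(geno.calls).any():
        lods = _all_marker_lods_complete(values, geno.calls)
        usable = np.full(n_genes, values.shape[1] >= 3)
    else:
        lods = np.zeros((n_genes, n_markers), dtype=float)
        usable = np.zeros(n_genes, dtype=bool)
        for j in range(n_markers):
            lods[:, j], n = _marker_lods(values, present, geno.calls[:, j])
            usable |= n >= 3
    if not usable.all():
        bad = [g for g, u in zip(expr.genes, usable) if not u]
        raise ValueError(
            f"genes with <3 complete strains at every marker: {bad[:5]}"
        )
    scans = []
    for i, gene in enumerate(expr.genes):
        peak = int(np.argmax(lods[i]))  # first max: lowest (chrom, pos) wins ties
        scans.append(
            LodScan(
                gene_id=gene,
                lods=lods[i],
                peak_index=peak,
                peak_marker=geno.markers[peak],
                peak_lod=float(lods[i, peak]),
            )
        )
    n_capped = int((lods >= LOD_CAP).sum())
    if n_capped:
        logger.info("capped %d perfect-fit LOD values at %.0f", n_capped, LOD_CAP)
    return scans


def lod_scan(y: np.ndarray | pd.Series, geno: GenotypeMatrix, gene_id: str = "gene") -> LodScan:
    """Scan a single strain-level expression vector against all markers."""
    if isinstance(y, pd.Series):
        values = pd.DataFrame([y.to_numpy(dtype=float)], index=[gene_id], columns=y.index)
        expr = ExpressionMatrix(values)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != geno.n_strains:
            raise ValueError("expression vector length != number of strains")
        expr = ExpressionMatrix(
            pd.DataFrame([y], index=[gene_id], columns=geno.strains)
        )
    return scan_all(expr, geno)[0]


def call_eqtls(
    scans: list[LodScan],
    annotation: GeneAnnotation,
    config: PipelineConfig | None = None,
) -> list[EqtlRecord]:
    """One record per gene with peak LOD at or above threshold.

    kind is "cis" iff the peak marker sits on the gene's chromosome
    within cis_window_bp of its transcription start, else "trans".
    """
    config = config or PipelineConfig()
    records = []
    for scan in scans:
        if scan.gene_id not in annotation:
            raise ValueError(f"gene {scan.gene_id!r} missing from annotation")
        if scan.peak_lod < config.lod_threshold:
            continue
        chrom = annotation.chrom(scan.gene_id)
        start = annotation.start(scan.gene_id)
        m = scan.peak_marker
        cis = m.chrom == chrom and abs(m.pos - start) <= config.cis_window_bp
        records.append(
            EqtlRecord(
                gene_id=scan.gene_id,
                gene_chrom=chrom,
                gene_start=start,
                peak_marker=m.id,
                peak_chrom=m.chrom,
                peak_pos=m.pos,
                peak_lod=scan.peak_lod,
                kind="cis" if cis else "trans",
            )
        )
    return records


def eqtls_to_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    from .io import EQTL_COLUMNS

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "gene_chrom": r.gene_chrom,
                "gene_start": r.gene_start,
                "peak_marker": r.peak_marker,
                "peak_chrom": r.peak_chrom,
                "peak_pos": r.peak_pos,
                "peak_lod": r.peak_lod,
                "kind": r.kind,
            }
            for r in records
        ],
        columns=EQTL_COLUMNS,
    )


def flag_probe_snps(
    probes: list[GenomicRegion],
    snps: list[tuple[GenomicRegion, float]],
    quality_min: float = 100.0,
) -> list[ProbeSnpFlag]:
    """Flag probes overlapped (>=1 bp) by a SNP with score strictly
    above ``quality_min``.

    Probe labels identify the gene/probe.  Flagged genes are reported
    alongside clusters so they can be excluded on request.
    """
    flags = []
    qualified = [(r, s) for r, s in snps if s > quality_min]
    for probe in probes:
        hits = [(r, s) for r, s in qualified if probe.overlaps(r)]
        if hits:
            flags.append(
                ProbeSnpFlag(
                    gene_id=probe.label or f"{probe.chrom}:{probe.start}-{probe.end}",
                    snp_ids=tuple(
                        r.label or f"{r.chrom}:{r.start}" for r, _ in hits
                    ),
                    max_score=max(s for _, s in hits),
                )
            )
    return flags
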
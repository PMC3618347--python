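"""Cross-dataset comparison of cluster-containing regions, and import
of externally computed eQTL lists.

Overlap is directional: for each region of set A we ask whether any
region of set B intersects it by >= 1 bp (half-open semantics; cluster
spans, not flank-augmented regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .types import EqtlRecord, GenomicRegion

__all__ = ["OverlapReport", "region_overlap", "import_external_eqtl_list"]


@dataclass
class OverlapReport:
    label_a: str
    label_b: str
    n_a: int
    n_overlapping: int
    pairs: list[tuple[GenomicRegion, GenomicRegion]]

    @property
    def proportion(self) -> float:
        return self.n_overlapping / self.n_a if self.n_a else 0.0


def region_overlap(
    regions_a: list[GenomicRegion],
    regions_b: list[GenomicRegion],
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapReport:
    """Proportion of A's regions intersecting >= 1 region of B.

    Chromosomes present in only one set are warned about and treated as
    non-overlapping (they cannot match by construction).
    """
    chroms_a = {r.chrom for r in regions_a}
    chroms_b = {r.chrom for r in regions_b}
    only = chroms_a ^ chroms_b
    if only:
        warnings.warn(
            f"chromosomes present in one set only: {sorted(only)}", stacklevel=2
        )
    pairs = []
    n_hit = 0
    for a in regions_a:
        hits = [b for b in regions_b if a.overlaps(b)]
        if hits:
            n_hit += 1
            pairs.extend((a, b) for b in hits)
    return OverlapReport(label_a, label_b, len(regions_a), n_hit, pairs)


def overlap_to_frame(report: OverlapReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_a": report.label_a,
                "set_b": report.label_b,
                "a_chrom": a.chrom,
                "a_start": a.start,
                "a_end": a.end,
                "b_chrom": b.chrom,
                "b_start": b.start,
                "b_end": b.end,
            }
            for a, b in report.pairs
        ],
        columns=[
            "set_a",
            "set_b",
            "a_chrom",
            "a_start",
            "a_end",
            "b_chrom",
            "b_start",
            "b_end",
        ],
    )


EXTERNAL_COLUMNS = ["gene_id", "gene_chrom", "gene_start", "peak_chrom", "peak_pos", "fdr"]


def import_external_eqtl_list(
    path,
    fdr_threshold: float = 0.2,
    config: PipelineConfig | None = None,
) -> list[EqtlRecord]:
    """Read an externally computed eQTL table and filter by FDR.

    Rows with FDR <= threshold (inclusive) are retained; cis/trans is
    assigned with the same 1 Mb gene-start rule used for scans run here.
    Imported lists are taken as-is — never re-thresholded by LOD.
    Expected TSV columns: gene_id, gene_chrom, gene_start (1-based),
    peak_chrom, peak_pos, fdr; optional score.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype={"gene_chrom": str, "peak_chrom": str})
    missing = [c for c in EXTERNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    kept = df[df["fdr"] <= fdr_threshold]
    records = []
    for row in kept.itertuples():
        gene_start = int(row.gene_start) - 1  # file is 1-based
        cis = (
            row.peak_chrom == row.gene_chrom
            and abs(int(row.peak_pos) - gene_start) <= config.cis_window_bp
        )
        records.append(
            EqtlRecord(
                gene_id=str(row.gene_id),
                gene_chrom=str(row.gene_chrom),
                gene_start=gene_start,
                peak_marker=f"{row.peak_chrom}:{row.peak_pos}",
                peak_chrom=str(row.peak_chrom),
                peak_pos=int(row.peak_pos),
                peak_lod=float("nan"),
                kind="cis" if cis else "trans",
            )
        )
    return records
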
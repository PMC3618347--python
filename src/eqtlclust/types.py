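"""Core domain containers shared by every pipeline stage.

Coordinate convention: every interval in the package is 0-based,
half-open ``[start, end)`` — the BED convention.  Gene starts read from
1-based annotation files are converted once, on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "Marker",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "FeatureTrack",
    "LodScan",
    "EqtlRecord",
    "ProbeSnpFlag",
    "Cluster",
    "HaplotypeBlock",
]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        """Half-open overlap: abutting intervals do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Marker:
    """A biallelic genotyping marker.

    ``informative`` means polymorphic within the loaded panel: at least
    one strain carries each parental allele.
    """

    id: str
    chrom: str
    pos: int
    informative: bool = True


class GenotypeMatrix:
    """Strain x marker parental-allele calls for an inbred panel.

    Calls are stored as a float array with 0.0 for the first parental
    allele (A), 1.0 for the second (B) and NaN for missing.  Markers are
    kept sorted by (chrom, pos); positions are strictly increasing
    within each chromosome.
    """

    def __init__(self, strains: list[str], markers: list[Marker], calls: np.ndarray):
        calls = np.asarray(calls, dtype=float)
        if calls.shape != (len(strains), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(strains)} strains x {len(markers)} markers"
            )
        order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos))
        markers = [markers[i] for i in order]
        calls = calls[:, order]
        for a, b in zip(markers, markers[1:]):
            if a.chrom == b.chrom and a.pos >= b.pos:
                raise ValueError(
                    f"marker positions not strictly increasing on {a.chrom}: "
                    f"{a.id}@{a.pos} then {b.id}@{b.pos}"
                )
        self.strains = list(strains)
        self.markers = markers
        self.calls = calls
        self._marker_col = {m.id: j for j, m in enumerate(markers)}
        if len(self._marker_col) != len(markers):
            raise ValueError("duplicate marker ids")
        # recompute informativeness from the calls actually loaded
        self.markers = [
            Marker(m.id, m.chrom, m.pos, informative=self._is_informative(j))
            for j, m in enumerate(markers)
        ]

    def _is_informative(self, col: int) -> bool:
        c = self.calls[:, col]
        c = c[~np.isnan(c)]
        return bool(c.size and (c == 0).any() and (c == 1).any())

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self._marker_col[marker_id]]

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self._marker_col[marker_id]]

    def informative(self) -> list[Marker]:
        return [m for m in self.markers if m.informative]

    def subset_strains(self, strains: list[str]) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in strains]
        return GenotypeMatrix(strains, self.markers, self.calls[idx, :])


class ExpressionMatrix:
    """Gene x strain log2 expression with an optional detection layer.

    ``values`` is a genes-by-strains DataFrame.  ``detection`` (if
    present) is a boolean DataFrame whose columns are a (strain,
    replicate) MultiIndex: one detection call per biological replicate.
    """

    def __init__(self, values: pd.DataFrame, detection: pd.DataFrame | None = None):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if values.shape[0] and values.shape[1] and values.isna().all(axis=0).any():
            bad = values.columns[values.isna().all(axis=0)].tolist()
            raise ValueError(f"strain columns entirely missing: {bad}")
        if detection is not None:
            if not detection.index.equals(values.index):
                raise ValueError("detection layer gene ids differ from expression")
            if detection.columns.nlevels != 2:
                raise ValueError("detection columns must be (strain, replicate) pairs")
        self.values = values
        self.detection = detection

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def strains(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        det = self.detection.loc[genes] if self.detection is not None else None
        return ExpressionMatrix(self.values.loc[genes], det)


class GeneAnnotation:
    """Gene id -> (chrom, transcription start, strand).

    Starts are stored 0-based.  Strand is '+' or '-'.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in annotation")
        if (df["start"] < 0).any():
            raise ValueError("negative gene start in annotation")
        self.df = df

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    def chrom(self, gene_id: str) -> str:
        return self.df.at[gene_id, "chrom"]

    def start(self, gene_id: str) -> int:
        return int(self.df.at[gene_id, "start"])

    def strand(self, gene_id: str) -> str:
        return self.df.at[gene_id, "strand"]

    def subset(self, genes: list[str]) -> "GeneAnnotation":
        return GeneAnnotation(self.df.loc[genes])

    def positions(self, genes: list[str] | None = None) -> pd.DataFrame:
        """(gene_id, chrom, start) table, one row per gene."""
        df = self.df if genes is None else self.df.loc[genes]
        out = df[["chrom", "start"]].copy()
        out.insert(0, "gene_id", df.index)
        return out.reset_index(drop=True)


class FeatureTrack:
    """A labelled set of genomic intervals (TE insertions, binding sites...).

    Backed by a DataFrame with columns chrom, start, end, label,
    class_label (e.g. SINE/LTR/LINE), status (polymorphic|fixed),
    orientation.
    """

    COLUMNS = ["chrom", "start", "end", "label", "class_label", "status", "orientation"]

    def __init__(self, name: str, df: pd.DataFrame):
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"feature track missing column {col!r}")
        df = df.copy()
        for col, default in (
            ("label", None),
            ("class_label", "feature"),
            ("status", "n/a"),
            ("orientation", "n/a"),
        ):
            if col not in df.columns:
                df[col] = default
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError(f"track {name!r} has features with start >= end")
        self.name = name
        self.df = df[self.COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def regions(self) -> list[GenomicRegion]:
        return [
            GenomicRegion(r.chrom, int(r.start), int(r.end), r.label)
            for r in self.df.itertuples()
        ]


@dataclass
class LodScan:
    """Single-marker LOD curve for one transcript."""

    gene_id: str
    lods: np.ndarray  # one value per marker, aligned with the genotype matrix
    peak_index: int
    peak_marker: Marker
    peak_lod: float


@dataclass(frozen=True)
class EqtlRecord:
    """A called eQTL: a transcript's peak marker at or above threshold."""

    gene_id: str
    gene_chrom: str
    gene_start: int
    peak_marker: str
    peak_chrom: str
    peak_pos: int
    peak_lod: float
    kind: str  # "cis" | "trans"


@dataclass(frozen=True)
class ProbeSnpFlag:
    """A probe overlapped by at least one high-quality polymorphic SNP."""

    gene_id: str
    snp_ids: tuple[str, ...]
    max_score: float


@dataclass
class Cluster:
    """A genomic gene group: cis-eQTL cluster, matched control, random
    box, or single-eQTL region.

    For cis and control clusters the span runs from the first to the
    last member gene start (half-open).  Random and single regions have
    no members.
    """

    kind: str  # "cis" | "control" | "random" | "single"
    chrom: str
    span: GenomicRegion
    members: tuple[str, ...] = ()
    window_bp: int | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        return self.span.length


@dataclass(frozen=True)
class HaplotypeBlock:
    """Minimal haplotype block: the interval between two consecutive
    informative markers, with no informative marker in its interior."""

    chrom: str
    start: int
    end: int
    left_marker: str
    right_marker: str

    @property
    def span(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end)
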
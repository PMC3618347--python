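"""Readers and writers for the tabular and interval formats the
pipeline consumes and emits.

All TSV files carry a header row.  BED files are 0-based half-open
BED3+ with optional name column; writer/reader pairs round-trip
bit-exactly on valid input.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    FeatureTrack,
    GeneAnnotation,
    GenomicRegion,
    GenotypeMatrix,
    Marker,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_feature_bed",
    "write_features_bed",
    "write_regions_bed",
    "read_regions_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_eqtl_table",
    "write_eqtl_table",
]

# parental-allele call codes: A/B the two parents, U unknown.
# Heterozygous calls (H) are treated as missing: an inbred panel is
# homozygous by construction, so a het call is a genotyping artifact.
_CALL_CODES = {"A": 0.0, "B": 1.0, "U": np.nan, "H": np.nan}
_CODE_CHARS = {0.0: "A", 1.0: "B"}


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Load a marker x strain genotype TSV.

    Columns: ``marker``, ``chrom``, ``pos`` then one column per strain
    with calls in {A, B, U, H}.  Markers are returned sorted by
    (chrom, pos) with informativeness recomputed from the loaded calls.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("marker", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["marker"].duplicated().any():
        dupes = df["marker"][df["marker"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate marker ids: {dupes[:5]}")
    strain_cols = [c for c in df.columns if c not in ("marker", "chrom", "pos")]
    if not strain_cols:
        raise ValueError(f"{path}: no strain columns")
    calls = np.empty((len(strain_cols), len(df)), dtype=float)
    for j, strain in enumerate(strain_cols):
        col = df[strain].astype(str).str.strip()
        bad = ~col.isin(_CALL_CODES)
        if bad.any():
            row = df["marker"][bad].iloc[0]
            raise ValueError(
                f"{path}: unknown call code {col[bad].iloc[0]!r} "
                f"at marker {row!r}, strain {strain!r}"
            )
        calls[j] = col.map(_CALL_CODES).to_numpy()
    markers = [
        Marker(str(m), str(c), int(p))
        for m, c, p in zip(df["marker"], df["chrom"], df["pos"])
    ]
    return GenotypeMatrix(strain_cols, markers, calls)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    rows = {
        "marker": [m.id for m in geno.markers],
        "chrom": [m.chrom for m in geno.markers],
        "pos": [m.pos for m in geno.markers],
    }
    for i, strain in enumerate(geno.strains):
        rows[strain] = [
            "U" if np.isnan(v) else _CODE_CHARS[v] for v in geno.calls[i]
        ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | Path, detection_path: str | Path | None = None
) -> ExpressionMatrix:
    """Load a gene x strain log2 expression TSV (first column gene_id).

    The optional detection TSV has one 0/1 column per replicate, named
    ``<strain>:<replicate>``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    detection = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0)
        det.index = det.index.astype(str)
        pairs = []
        for col in det.columns:
            if ":" not in col:
                raise ValueError(
                    f"{detection_path}: detection column {col!r} is not "
                    "'strain:replicate'"
                )
            strain, rep = col.rsplit(":", 1)
            pairs.append((strain, rep))
        det.columns = pd.MultiIndex.from_tuples(pairs, names=["strain", "replicate"])
        detection = det.astype(bool)
    return ExpressionMatrix(values, detection)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    detection_path: str | Path | None = None,
) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")
    if detection_path is not None and expr.detection is not None:
        flat = expr.detection.astype(int).copy()
        flat.columns = [f"{s}:{r}" for s, r in flat.columns]
        flat.to_csv(detection_path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Load gene annotation TSV: gene_id, chrom, start (1-based), strand.

    Starts are converted to the package's 0-based convention on load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("gene_id", "chrom", "start", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.set_index("gene_id")
    df.index = df.index.astype(str)
    df["start"] = df["start"].astype(int) - 1
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.df[["chrom", "start", "strand"]].copy()
    out["start"] = out["start"] + 1  # back to the 1-based file convention
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_feature_bed(
    path: str | Path,
    name: str | None = None,
    class_label: str = "feature",
    status: str = "n/a",
    orientation: str = "n/a",
) -> FeatureTrack:
    """Load a BED3+ file into a FeatureTrack.

    Column 4 (if present) is kept as the per-feature label.  Track-level
    class/status/orientation annotations come from the caller (typically
    the config naming each track file).
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    labels: list[str | None] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            labels.append(fields[3] if len(fields) > 3 else None)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=int),
            "end": pd.Series(ends, dtype=int),
            "label": pd.Series(labels, dtype=object),
        }
    )
    df["class_label"] = class_label
    df["status"] = status
    df["orientation"] = orientation
    return FeatureTrack(name or path.stem, df)


def write_features_bed(track: FeatureTrack, path: str | Path) -> None:
    df = track.df.sort_values(["chrom", "start", "end"], kind="stable")
    with open(path, "w") as fh:
        for row in df.itertuples():
            if row.label is None or (isinstance(row.label, float) and np.isnan(row.label)):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def write_regions_bed(regions: list[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED, sorted by (chrom, start, end)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            if r.label is None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_regions_bed(path: str | Path) -> list[GenomicRegion]:
    track = read_feature_bed(path)
    return track.regions()


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC-style chrom.sizes file (chrom <TAB> length)."""
    sizes: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        if fields[0] in sizes:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


EQTL_COLUMNS = [
    "gene_id",
    "gene_chrom",
    "gene_start",
    "peak_marker",
    "peak_chrom",
    "peak_pos",
    "peak_lod",
    "kind",
]


def write_eqtl_table(eqtls: pd.DataFrame, path: str | Path) -> None:
    eqtls.to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_chrom": str, "peak_chrom": str})
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing eQTL columns: {sorted(missing)}")
    return df


def infer_chrom_sizes(
    geno: GenotypeMatrix | None = None,
    annotation: GeneAnnotation | None = None,
    tracks: list[FeatureTrack] | None = None,
    pad_bp: int = 1_000_000,
) -> dict[str, int]:
    """Infer usable chromosome lengths from the maximal coordinate seen
    in the inputs, plus a pad.  Used when no chrom.sizes file is given;
    flank clipping then never extends past observed data plus the pad.
    """
    maxima: dict[str, int] = {}

    def bump(chrom: str, pos: int) -> None:
        maxima[chrom] = max(maxima.get(chrom, 0), int(pos))

    if geno is not None:
        for m in geno.markers:
            bump(m.chrom, m.pos)
    if annotation is not None:
        for gene, row in annotation.df.iterrows():
            bump(row["chrom"], row["start"])
    for track in tracks or []:
        for row in track.df.itertuples():
            bump(row.chrom, row.end)
    if not maxima:
        raise ValueError("cannot infer chromosome sizes from empty inputs")
    warnings.warn(
        "chromosome sizes inferred from input coordinates; supply a "
        "chrom.sizes file for exact flank clipping",
        stacklevel=2,
    )
    return {c: v + pad_bp for c, v in maxima.items()}
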
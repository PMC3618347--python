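"""Pipeline configuration: the thresholds and window sizes that define
every stage, with the field-standard defaults.

Config files are flat ``key = value`` text; every run logs the fully
resolved configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig", "read_config", "write_config"]

CLUSTER_GAP_CHOICES = (250_000, 500_000, 750_000)
FLANK_CHOICES = (250_000, 500_000, 1_000_000)


@dataclass
class PipelineConfig:
    """Thresholds and window sizes for a full cluster-detection run.

    lod_threshold
        Genome-wide LOD detection threshold (3.3).
    cis_window_bp
        A peak within this distance of the gene start (same chromosome)
        makes the eQTL cis (1 Mb).
    max_gap_bp
        Maximum gap between consecutive cis-eQTL gene starts inside one
        cluster; 250, 500 or 750 kb.
    min_cluster_size
        Minimum member count of a reported cluster (3).
    flank_bp
        Flank added to each region before feature counting; 250, 500 or
        1000 kb.
    n_random_groups
        Number of random gene groups for the coexpression null (500).
    n_random_regions
        Number of random genomic boxes for the enrichment null.
    detection_fraction
        A gene is kept when detected in strictly more than this fraction
        of replicates in at least one strain (0.5).
    fdr_threshold_external
        FDR cutoff applied only when importing externally computed eQTL
        lists (0.2); never applied to LOD scans run here.
    """

    lod_threshold: float = 3.3
    cis_window_bp: int = 1_000_000
    max_gap_bp: int = 250_000
    min_cluster_size: int = 3
    flank_bp: int = 250_000
    n_random_groups: int = 500
    n_random_regions: int = 200
    rng_seed: int = 0
    fdr_threshold_external: float = 0.2
    detection_fraction: float = 0.5
    group_size_range: tuple[int, int] | None = None
    """Random-group size range; default follows the window variant
    (3-11 genes for 250 kb runs, 3-19 for 500 kb runs)."""

    def __post_init__(self) -> None:
        for name in ("cis_window_bp", "max_gap_bp", "flank_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if not 0 < self.detection_fraction < 1:
            raise ValueError("detection_fraction must be in (0, 1)")
        if self.max_gap_bp not in CLUSTER_GAP_CHOICES:
            raise ValueError(
                f"max_gap_bp must be one of {CLUSTER_GAP_CHOICES}, got {self.max_gap_bp}"
            )
        if self.flank_bp not in FLANK_CHOICES:
            raise ValueError(f"flank_bp must be one of {FLANK_CHOICES}, got {self.flank_bp}")

    @property
    def random_group_sizes(self) -> tuple[int, int]:
        if self.group_size_range is not None:
            return self.group_size_range
        return (3, 19) if self.max_gap_bp >= 500_000 else (3, 11)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_size_range"] = (
            None if self.group_size_range is None else list(self.group_size_range)
        )
        return d


_INT_FIELDS = {
    "cis_window_bp",
    "max_gap_bp",
    "min_cluster_size",
    "flank_bp",
    "n_random_groups",
    "n_random_regions",
    "rng_seed",
}
_FLOAT_FIELDS = {"lod_threshold", "fdr_threshold_external", "detection_fraction"}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file.

    Unknown keys are a hard error (misspelled thresholds must not be
    silently ignored).  Lines starting with '#' are comments.
    """
    kwargs: dict = {}
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in names:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key in _FLOAT_FIELDS:
            kwargs[key] = float(value)
        elif key == "group_size_range":
            lo, hi = (int(v) for v in value.split(","))
            kwargs[key] = (lo, hi)
        else:  # pragma: no cover - no other field kinds today
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for key, value in config.to_dict().items():
        if value is None:
            continue
        if isinstance(value, (list, tuple)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
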
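"""Feature-density enrichment over region groups.

Each region (cis cluster, control cluster, single-eQTL box, random box)
is grown by the configured flank, features overlapping it by >= 1 bp are
counted, and the density (features/Mb of flank-augmented, edge-clipped
length) is normalized by the mean density over the random boxes — so
the random group averages exactly 1 and every other value reads as fold
difference vs random.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .clusters import augment_flanks
from .types import Cluster, FeatureTrack, GenomicRegion, HaplotypeBlock

__all__ = [
    "count_features_in_region",
    "normalized_density",
    "compare_enrichment",
    "density_inside_vs_outside_blocks",
    "plot_enrichment",
]

logger = logging.getLogger(__name__)


def count_features_in_region(region: GenomicRegion, track: FeatureTrack) -> int:
    """Number of features overlapping the region by >= 1 bp (half-open
    semantics: an abutting feature does not count).  Each feature counts
    once regardless of overlap width."""
    df = track.df
    on = df["chrom"].to_numpy() == region.chrom
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    return int((on & (starts < region.end) & (ends > region.start)).sum())


def normalized_density(
    regions_by_kind: dict[str, list[Cluster]],
    track: FeatureTrack,
    flank_bp: int,
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Per-region feature densities, normalized by the random-group mean.

    Returns one row per region: kind, chrom, start/end of the
    flank-augmented region, count, length_mb, density, normalized.
    Raises if the random group's mean density is zero for this track.
    """
    if "random" not in regions_by_kind or not regions_by_kind["random"]:
        raise ValueError("normalized_density requires a non-empty 'random' group")
    rows = []
    for kind, clusters in regions_by_kind.items():
        for c in clusters:
            grown = augment_flanks(c.span, flank_bp, chrom_sizes[c.chrom])
            count = count_features_in_region(grown, track)
            length_mb = grown.length / 1e6
            rows.append(
                {
                    "track": track.name,
                    "kind": kind,
                    "chrom": grown.chrom,
                    "start": grown.start,
                    "end": grown.end,
                    "count": count,
                    "length_mb": length_mb,
                    "density": count / length_mb,
                }
            )
    df = pd.DataFrame(rows)
    random_mean = df.loc[df["kind"] == "random", "density"].mean()
    if random_mean == 0:
        raise ValueError(
            f"track {track.name!r}: random-region mean density is zero; "
            "cannot normalize"
        )
    df["normalized"] = df["density"] / random_mean
    return df


def _anova_p(samples) -> float:
    """One-way ANOVA p; a numerically negative-zero F (identical group
    means) is a no-effect result, reported as p = 1."""
    res = stats.f_oneway(*samples)
    p = float(res.pvalue)
    if np.isnan(p) and abs(float(res.statistic)) < 1e-9:
        return 1.0
    return p


def compare_enrichment(density_rows: pd.DataFrame) -> dict:
    """Test normalized-density differences across region kinds.

    Per track (feature class): one-way ANOVA across kinds plus Tukey HSD
    pairwise p-values.  Across tracks jointly: two-way ANOVA
    (kind x track) with the kind and track main effects and their
    interaction, plus Tukey HSD on kinds pooled over tracks.  All
    p-values are reported; nothing is thresholded.
    """
    out: dict = {"per_track": {}, "two_way": None}
    for track, sub in density_rows.groupby("track"):
        kinds = [k for k, s in sub.groupby("kind") if len(s) >= 2]
        entry: dict = {"anova_p": np.nan, "tukey": pd.DataFrame()}
        if len(kinds) >= 2:
            samples = [sub.loc[sub["kind"] == k, "normalized"] for k in kinds]
            entry["anova_p"] = _anova_p(samples)
            tk = pairwise_tukeyhsd(
                sub.loc[sub["kind"].isin(kinds), "normalized"],
                sub.loc[sub["kind"].isin(kinds), "kind"],
            )
            tdf = pd.DataFrame(
                tk.summary().data[1:], columns=[c.strip() for c in tk.summary().data[0]]
            )[["group1", "group2", "p-adj"]].rename(columns={"p-adj": "p"})
            tdf["p"] = tdf["p"].astype(float)
            entry["tukey"] = tdf
        else:
            entry["note"] = "fewer than 2 kinds with >= 2 regions"
        out["per_track"][track] = entry
    if density_rows["track"].nunique() >= 2 and density_rows["kind"].nunique() >= 2:
        model = ols("normalized ~ C(kind) * C(track)", data=density_rows).fit()
        table = anova_lm(model, typ=2)
        out["two_way"] = {
            "kind_p": float(table.loc["C(kind)", "PR(>F)"]),
            "track_p": float(table.loc["C(track)", "PR(>F)"]),
            "interaction_p": float(table.loc["C(kind):C(track)", "PR(>F)"]),
            "table": table,
        }
    return out


def density_inside_vs_outside_blocks(
    cis_regions: list[GenomicRegion],
    blocks: list[HaplotypeBlock],
    track: FeatureTrack,
) -> dict:
    """Paired comparison of feature density inside each (flank-grown)
    cis region vs the remainder of its containing haplotype block.

    A region is assigned to the block containing its midpoint; regions
    spanning a block boundary are assigned that way with a warning.
    Regions whose midpoint falls in no block are skipped.
    """
    inside, outside = [], []
    for region in cis_regions:
        mid = region.midpoint
        host = next(
            (
                b
                for b in blocks
                if b.chrom == region.chrom and b.start <= mid < b.end
            ),
            None,
        )
        if host is None:
            continue
        if region.start < host.start or region.end > host.end:
            warnings.warn(
                f"region {region.chrom}:{region.start}-{region.end} spans a "
                "block boundary; assigned by midpoint",
                stacklevel=2,
            )
        clipped = GenomicRegion(
            region.chrom,
            max(region.start, host.start),
            min(region.end, host.end),
        )
        n_in = count_features_in_region(clipped, track)
        len_in = clipped.length / 1e6
        n_blk = count_features_in_region(host.span, track)
        n_cross = n_in  # features overlapping the clipped region also overlap the block
        len_out = (host.span.length - clipped.length) / 1e6
        if len_in <= 0 or len_out <= 0:
            continue
        inside.append(n_in / len_in)
        outside.append(max(n_blk - n_cross, 0) / len_out)
    result = {
        "inside": inside,
        "outside": outside,
        "inside_mean": float(np.mean(inside)) if inside else np.nan,
        "outside_mean": float(np.mean(outside)) if outside else np.nan,
        "p": np.nan,
    }
    if len(inside) >= 2:
        result["p"] = float(stats.ttest_rel(inside, outside).pvalue)
    return result


def plot_enrichment(density_rows: pd.DataFrame, path) -> None:
    """Bar chart of group mean +/- SEM normalized density per track."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = (
        density_rows.groupby(["track", "kind"])["normalized"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    tracks = summary["track"].unique()
    fig, axes = plt.subplots(1, len(tracks), figsize=(4 * len(tracks), 4), squeeze=False)
    for ax, track in zip(axes[0], tracks):
        sub = summary[summary["track"] == track]
        ax.bar(sub["kind"], sub["mean"], yerr=sub["sem"], capsize=3)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_title(track)
        ax.set_ylabel("normalized density (fold vs random)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
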
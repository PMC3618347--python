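"""End-to-end orchestration: scan -> call eQTLs -> clusters -> nulls ->
coexpression -> enrichment, with every stage's tables written out.

The pipeline is a pure function of (inputs, config, seed): rerunning
with the same seed produces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .clusters import (
    adjacent_marker_ld,
    augment_flanks,
    build_control_clusters,
    cluster_heterogeneity,
    clusters_to_frame,
    detect_clusters,
    haplotype_blocks,
    sample_random_regions,
    single_eqtl_regions,
)
from .coexpression import (
    CoexpressionResult,
    block_coexpression,
    cluster_coexpression,
    compare_coexpression,
    random_gene_groups,
)
from .config import PipelineConfig, write_config
from .enrichment import (
    compare_enrichment,
    density_inside_vs_outside_blocks,
    normalized_density,
)
from .scan import call_eqtls, eqtls_to_frame, filter_detected_genes, scan_all
from .simulate import SimBundle, SimTruth
from .types import (
    Cluster,
    ExpressionMatrix,
    FeatureTrack,
    GeneAnnotation,
    GenotypeMatrix,
)

__all__ = ["PipelineResult", "run_pipeline", "load_inputs", "planted_recovery"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineResult:
    config: PipelineConfig
    eqtls: pd.DataFrame
    cis_clusters: list[Cluster]
    control_clusters: list[Cluster]
    control_report: dict
    single_regions: list[Cluster]
    random_regions: list[Cluster]
    blocks: list
    ld: pd.DataFrame
    coexpression: CoexpressionResult | None
    coexpr_values: pd.DataFrame
    block_coexpr: pd.DataFrame
    heterogeneity: pd.DataFrame
    enrichment: pd.DataFrame
    enrichment_tests: dict
    inside_outside: dict
    mean_expression: dict
    n_genes_input: int
    n_genes_detected: int

    @property
    def n_cis_eqtls(self) -> int:
        return int((self.eqtls["kind"] == "cis").sum()) if len(self.eqtls) else 0


def load_inputs(
    genotypes: str | Path,
    expression: str | Path,
    annotation: str | Path,
    detection: str | Path | None = None,
    chrom_sizes: str | Path | None = None,
    tracks: dict[str, str | Path] | None = None,
) -> tuple[GenotypeMatrix, ExpressionMatrix, GeneAnnotation, dict[str, int], dict[str, FeatureTrack]]:
    geno = eio.read_genotypes(genotypes)
    expr = eio.read_expression(expression, detection)
    ann = eio.read_annotation(annotation)
    loaded_tracks = {}
    for name, path in (tracks or {}).items():
        status = "polymorphic" if "polymorphic" in name else (
            "fixed" if "fixed" in name else "n/a"
        )
        loaded_tracks[name] = eio.read_feature_bed(path, name=name, status=status)
    if chrom_sizes is not None:
        sizes = eio.read_chrom_sizes(chrom_sizes)
    else:
        sizes = eio.infer_chrom_sizes(geno, ann, list(loaded_tracks.values()))
    return geno, expr, ann, sizes, loaded_tracks


def _check_strains(expr: ExpressionMatrix, geno: GenotypeMatrix) -> None:
    missing = sorted(set(expr.strains) - set(geno.strains))
    if missing:
        raise ValueError(
            f"strains present in expression but not in genotypes: {missing}"
        )


def planted_recovery(
    truth: SimTruth,
    cis_clusters: list[Cluster],
    jaccard_threshold: float = 0.75,
) -> dict:
    """Score detected cis clusters against the planted ground truth.

    A planted cluster counts as recovered when some detected cluster's
    member set reaches the Jaccard threshold against it.
    """
    detected_sets = [set(c.members) for c in cis_clusters]
    per_cluster = []
    for planted in truth.planted_clusters:
        target = set(planted.gene_ids)
        best = 0.0
        for d in detected_sets:
            j = len(d & target) / len(d | target)
            best = max(best, j)
        per_cluster.append(best)
    recovered = sum(j >= jaccard_threshold for j in per_cluster)
    return {
        "n_planted": len(per_cluster),
        "n_recovered": recovered,
        "recovery": recovered / len(per_cluster) if per_cluster else np.nan,
        "jaccard": per_cluster,
    }


def run_pipeline(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    chrom_sizes: dict[str, int],
    tracks: dict[str, FeatureTrack] | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage; optionally write the full report bundle."""
    config = config or PipelineConfig()
    tracks = tracks or {}
    rng = np.random.default_rng(config.rng_seed)
    _check_strains(expr, geno)
    n_input = expr.n_genes

    # --- detection filter ------------------------------------------------
    if expr.detection is not None:
        expr = filter_detected_genes(expr, config.detection_fraction)
    logger.info("stage detect: %d of %d genes retained", expr.n_genes, n_input)

    # --- eQTL scan --------------------------------------------------------
    scans = scan_all(expr, geno)
    records = call_eqtls(scans, annotation, config)
    eqtls = eqtls_to_frame(records)
    cis = eqtls[eqtls["kind"] == "cis"]
    logger.info(
        "stage scan: %d eQTLs (%d cis, %d trans)",
        len(eqtls),
        len(cis),
        len(eqtls) - len(cis),
    )

    # --- clusters and null region sets -----------------------------------
    cis_positions = cis.rename(columns={"gene_chrom": "chrom", "gene_start": "start"})[
        ["gene_id", "chrom", "start"]
    ]
    cis_clusters = detect_clusters(
        cis_positions, config.max_gap_bp, config.min_cluster_size, kind="cis"
    )
    detected_positions = annotation.positions(expr.genes)
    control_clusters, control_report = build_control_clusters(
        detected_positions, cis_clusters, config.max_gap_bp, config.min_cluster_size
    )
    member_genes = {g for c in cis_clusters for g in c.members}
    singleton_positions = cis_positions[~cis_positions["gene_id"].isin(member_genes)]
    mean_span = (
        int(np.mean([c.span_bp for c in cis_clusters])) if cis_clusters else None
    )
    single_regions = (
        single_eqtl_regions(singleton_positions, mean_span, chrom_sizes)
        if mean_span
        else []
    )
    if cis_clusters:
        sizes = [c.span_bp for c in cis_clusters]
        size_list = [sizes[i % len(sizes)] for i in range(config.n_random_regions)]
        random_regions = sample_random_regions(
            chrom_sizes,
            size_list,
            1,
            exclusions=[c.span for c in cis_clusters],
            rng=rng,
        )
    else:
        random_regions = []
    blocks = haplotype_blocks(geno)
    ld = adjacent_marker_ld(geno)
    logger.info(
        "stage clusters: %d cis, %d control, %d single, %d random, %d blocks",
        len(cis_clusters),
        len(control_clusters),
        len(single_regions),
        len(random_regions),
        len(blocks),
    )

    # --- coexpression -----------------------------------------------------
    coexpr_rows = []
    groups: dict[str, list[float]] = {}
    for kind, cluster_list in (("cis", cis_clusters), ("control", control_clusters)):
        vals = []
        for c in cluster_list:
            try:
                v = cluster_coexpression(list(c.members), expr)
            except ValueError:
                continue
            vals.append(v)
            coexpr_rows.append(
                {"kind": kind, "chrom": c.chrom, "span_start": c.span.start,
                 "span_end": c.span.end, "n_members": c.n_members, "mean_abs_r": v}
            )
        if vals:
            groups[kind] = vals
    random_vals, _ = random_gene_groups(
        expr.genes,
        config.random_group_sizes,
        config.n_random_groups,
        expr,
        rng=rng,
    )
    groups["random"] = random_vals
    coexpr_rows.extend(
        {"kind": "random", "chrom": "", "span_start": -1, "span_end": -1,
         "n_members": -1, "mean_abs_r": v}
        for v in random_vals
    )
    coexpr_values = pd.DataFrame(
        coexpr_rows,
        columns=["kind", "chrom", "span_start", "span_end", "n_members", "mean_abs_r"],
    )
    comparable = {k: v for k, v in groups.items() if len(v) >= 2}
    coexpression = (
        compare_coexpression(comparable) if len(comparable) >= 2 else None
    )
    block_coexpr = block_coexpression(blocks, annotation, expr)

    # mean expression level per group (cis vs control member genes)
    mean_expression: dict = {}
    cis_members = [g for c in cis_clusters for g in c.members]
    control_members = [g for c in control_clusters for g in c.members]
    if cis_members and control_members:
        a = expr.values.loc[cis_members].to_numpy().mean()
        b = expr.values.loc[control_members].to_numpy().mean()
        from scipy import stats as _st

        p = _st.ttest_ind(
            expr.values.loc[cis_members].mean(axis=1),
            expr.values.loc[control_members].mean(axis=1),
        ).pvalue
        mean_expression = {"cis": float(a), "control": float(b), "p": float(p)}

    # --- heterogeneity ----------------------------------------------------
    het_rows = []
    for c in cis_clusters:
        try:
            consistent, both = cluster_heterogeneity(c, expr, annotation)
        except ValueError:
            continue
        het_rows.append(
            {
                "chrom": c.chrom,
                "span_start": c.span.start,
                "span_end": c.span.end,
                "direction_consistent": consistent,
                "both_strands": both,
            }
        )
    heterogeneity = pd.DataFrame(
        het_rows,
        columns=["chrom", "span_start", "span_end", "direction_consistent", "both_strands"],
    )

    # --- enrichment -------------------------------------------------------
    enrichment = pd.DataFrame()
    enrichment_tests: dict = {}
    inside_outside: dict = {}
    regions_by_kind = {
        "cis": cis_clusters,
        "control": control_clusters,
        "single": single_regions,
        "random": random_regions,
    }
    regions_by_kind = {k: v for k, v in regions_by_kind.items() if v}
    if tracks and cis_clusters and random_regions:
        frames = [
            normalized_density(regions_by_kind, track, config.flank_bp, chrom_sizes)
            for track in tracks.values()
        ]
        enrichment = pd.concat(frames, ignore_index=True)
        enrichment_tests = compare_enrichment(enrichment)
        grown_cis = [
            augment_flanks(c.span, config.flank_bp, chrom_sizes[c.chrom])
            for c in cis_clusters
        ]
        for name, track in tracks.items():
            inside_outside[name] = density_inside_vs_outside_blocks(
                grown_cis, blocks, track
            )

    result = PipelineResult(
        config=config,
        eqtls=eqtls,
        cis_clusters=cis_clusters,
        control_clusters=control_clusters,
        control_report=control_report,
        single_regions=single_regions,
        random_regions=random_regions,
        blocks=blocks,
        ld=ld,
        coexpression=coexpression,
        coexpr_values=coexpr_values,
        block_coexpr=block_coexpr,
        heterogeneity=heterogeneity,
        enrichment=enrichment,
        enrichment_tests=enrichment_tests,
        inside_outside=inside_outside,
        mean_expression=mean_expression,
        n_genes_input=n_input,
        n_genes_detected=expr.n_genes,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def run_pipeline_on_bundle(
    bundle: SimBundle,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    return run_pipeline(
        bundle.genotypes,
        bundle.expression,
        bundle.annotation,
        bundle.chrom_sizes,
        bundle.tracks,
        config,
        out_dir,
    )


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format=_FLOAT_FMT)

    write_config(result.config, out / "config.txt")
    tsv(result.eqtls, "eqtls.tsv")
    for kind, clusters in (
        ("cis", result.cis_clusters),
        ("control", result.control_clusters),
        ("single", result.single_regions),
        ("random", result.random_regions),
    ):
        tsv(clusters_to_frame(clusters), f"clusters_{kind}.tsv")
        eio.write_regions_bed([c.span for c in clusters], out / f"clusters_{kind}.bed")
    tsv(
        pd.DataFrame(
            [
                {
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "left_marker": b.left_marker,
                    "right_marker": b.right_marker,
                }
                for b in result.blocks
            ],
            columns=["chrom", "start", "end", "left_marker", "right_marker"],
        ),
        "haplotype_blocks.tsv",
    )
    tsv(result.ld, "adjacent_marker_ld.tsv")
    tsv(result.coexpr_values, "coexpression_values.tsv")
    if result.coexpression is not None:
        summary = pd.DataFrame(
            [
                {
                    "kind": k,
                    "n": len(result.coexpression.values[k]),
                    "mean_abs_r": result.coexpression.means[k],
                    "sd": result.coexpression.sds[k],
                }
                for k in result.coexpression.means
            ]
        )
        tsv(summary, "coexpression_summary.tsv")
        tsv(result.coexpression.pairwise_p, "coexpression_pairwise.tsv")
    tsv(result.block_coexpr, "block_coexpression.tsv")
    tsv(result.heterogeneity, "heterogeneity.tsv")
    if len(result.enrichment):
        tsv(result.enrichment, "enrichment_regions.tsv")
        summary = (
            result.enrichment.groupby(["track", "kind"])["normalized"]
            .agg(["count", "mean", "sem"])
            .reset_index()
        )
        tsv(summary, "enrichment_summary.tsv")
        rows = []
        for track, entry in result.enrichment_tests["per_track"].items():
            rows.append({"track": track, "test": "anova_kind", "p": entry["anova_p"]})
            for t in entry["tukey"].itertuples():
                rows.append(
                    {
                        "track": track,
                        "test": f"tukey {t.group1} vs {t.group2}",
                        "p": t.p,
                    }
                )
        two_way = result.enrichment_tests.get("two_way")
        if two_way:
            rows.append({"track": "all", "test": "two_way_kind", "p": two_way["kind_p"]})
            rows.append({"track": "all", "test": "two_way_track", "p": two_way["track_p"]})
            rows.append(
                {"track": "all", "test": "two_way_interaction", "p": two_way["interaction_p"]}
            )
        tsv(pd.DataFrame(rows, columns=["track", "test", "p"]), "enrichment_tests.tsv")
        io_rows = [
            {
                "track": name,
                "inside_mean": d["inside_mean"],
                "outside_mean": d["outside_mean"],
                "n": len(d["inside"]),
                "p": d["p"],
            }
            for name, d in result.inside_outside.items()
        ]
        tsv(
            pd.DataFrame(io_rows, columns=["track", "inside_mean", "outside_mean", "n", "p"]),
            "block_inside_outside.tsv",
        )
    counts = {
        "n_genes_input": result.n_genes_input,
        "n_genes_detected": result.n_genes_detected,
        "n_eqtls": int(len(result.eqtls)),
        "n_cis_eqtls": result.n_cis_eqtls,
        "n_cis_clusters": len(result.cis_clusters),
        "n_control_clusters": len(result.control_clusters),
        "n_single_regions": len(result.single_regions),
        "n_random_regions": len(result.random_regions),
        "n_haplotype_blocks": len(result.blocks),
        "control_match": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in result.control_report.items()
        },
        "mean_expression": result.mean_expression,
        "seed": result.config.rng_seed,
    }
    (out / "run_summary.json").write_text(json.dumps(counts, indent=1, sort_keys=True))
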
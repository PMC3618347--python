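"""Generator contracts: Markov genotype mosaics, the planted expression
model, and piecewise-Poisson feature tracks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eqtlclust as ec
from eqtlclust.simulate import (
    SimConfig,
    simulate_annotation,
    simulate_bundle,
    simulate_expression,
    simulate_feature_track,
    simulate_genotypes,
)


def small_cfg(**kw) -> SimConfig:
    base = dict(
        n_strains=24,
        n_chrom=2,
        chrom_length_bp=50_000_000,
        n_markers=100,
        n_genes=200,
        n_planted_clusters=4,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenotypes:
    def test_zero_switch_prob_constant_chains(self):
        geno = simulate_genotypes(small_cfg(marker_switch_prob=0.0), seed=0)
        per_chrom = {m.chrom for m in geno.markers}
        for chrom in per_chrom:
            cols = [j for j, m in enumerate(geno.markers) if m.chrom == chrom]
            block = geno.calls[:, cols]
            assert (block == block[:, [0]]).all()

    def test_half_switch_prob_no_adjacent_ld(self):
        cfg = small_cfg(marker_switch_prob=0.499, n_strains=200)
        geno = simulate_genotypes(cfg, seed=1)
        ld = ec.adjacent_marker_ld(geno)
        assert ld["r2"].mean() < 0.1

    def test_flip_frequency_matches_switch_prob(self):
        # Monte-Carlo frequency oracle: over >= 1e4 strain-intervals the
        # empirical flip rate lies in the binomial 99% CI around p.
        cfg = small_cfg(n_strains=150, n_markers=100, marker_switch_prob=0.10)
        geno = simulate_genotypes(cfg, seed=2)
        flips = total = 0
        for chrom in {m.chrom for m in geno.markers}:
            cols = [j for j, m in enumerate(geno.markers) if m.chrom == chrom]
            block = geno.calls[:, cols]
            flips += int((np.diff(block, axis=1) != 0).sum())
            total += block.shape[0] * (block.shape[1] - 1)
        assert total >= 10_000
        lo, hi = stats.binom.interval(0.99, total, cfg.marker_switch_prob)
        assert lo <= flips <= hi

    def test_all_calls_homozygous(self):
        geno = simulate_genotypes(small_cfg(), seed=3)
        assert np.isin(geno.calls, [0.0, 1.0]).all()


class TestExpression:
    def _bundle_parts(self, cfg, seed=0):
        geno = simulate_genotypes(cfg, seed)
        ann, truth = simulate_annotation(cfg, geno, seed + 1)
        expr = simulate_expression(geno, ann, truth, cfg, seed + 2)
        return geno, ann, truth, expr

    def test_null_model_rarely_reaches_threshold(self):
        # beta=0, rho=0: genome-wide peak LOD < 3.3 for >= 95% of 100
        # independent null transcripts at 24 strains.
        cfg = small_cfg(beta=0.0, rho_latent=0.0, n_genes=100, n_planted_clusters=2)
        geno, ann, truth, expr = self._bundle_parts(cfg)
        scans = ec.scan_all(expr, geno)
        frac_below = np.mean([s.peak_lod < 3.3 for s in scans])
        assert frac_below >= 0.95

    def test_within_cluster_correlation_matches_closed_form(self):
        # latent factor only: theoretical |r| = rho^2/(rho^2+sigma^2)
        rho = np.sqrt(3.0)  # -> |r| = 0.75 with sigma=1
        cfg = small_cfg(n_strains=200, beta=0.0, rho_latent=rho, genes_per_cluster=4)
        _, _, truth, expr = self._bundle_parts(cfg, seed=5)
        expected = rho**2 / (rho**2 + cfg.sigma**2)
        vals = [
            ec.cluster_coexpression(list(c.gene_ids), expr)
            for c in truth.planted_clusters
        ]
        assert abs(np.mean(vals) - expected) < 0.1

    def test_default_parameters_give_target_coexpression(self):
        cfg = small_cfg(n_strains=200)
        assert abs(cfg.expected_within_cluster_abs_r() - 0.75) < 1e-12
        _, _, truth, expr = self._bundle_parts(cfg, seed=6)
        vals = [
            ec.cluster_coexpression(list(c.gene_ids), expr)
            for c in truth.planted_clusters
        ]
        assert abs(np.mean(vals) - 0.75) < 0.1

    def test_genes_in_different_clusters_uncorrelated(self):
        cfg = small_cfg(n_strains=200, beta=0.0, rho_latent=np.sqrt(3.0))
        _, _, truth, expr = self._bundle_parts(cfg, seed=7)
        a = truth.planted_clusters[0].gene_ids[0]
        b = truth.planted_clusters[1].gene_ids[0]
        r = np.corrcoef(
            expr.values.loc[a].to_numpy(), expr.values.loc[b].to_numpy()
        )[0, 1]
        assert abs(r) < 0.15

    def test_planted_members_are_consecutive_genes(self):
        cfg = small_cfg()
        _, ann, truth, _ = self._bundle_parts(cfg, seed=8)
        ordered = ann.df.sort_values(["chrom", "start"]).index.tolist()
        for cluster in truth.planted_clusters:
            idx = [ordered.index(g) for g in cluster.gene_ids]
            assert idx == list(range(min(idx), min(idx) + len(idx)))
            marker = cluster.marker_id
            # driving marker inside the planted span
            assert cluster.span.start <= _marker_pos(marker) <= cluster.span.end

    def test_unknown_planted_gene_is_error(self):
        cfg = small_cfg()
        geno = simulate_genotypes(cfg, 0)
        ann, truth = simulate_annotation(cfg, geno, 1)
        from dataclasses import replace

        truth.planted_clusters[0] = replace(
            truth.planted_clusters[0], gene_ids=("nonexistent",)
        )
        with pytest.raises(ValueError, match="not in annotation"):
            simulate_expression(geno, ann, truth, cfg, 2)


def _marker_pos(marker_id: str) -> int:
    # marker ids encode chrom and index; recover position from a fresh
    # genotype panel with the same config used in the test
    chrom, idx = marker_id.split("_m")
    per_chrom = 50  # 100 markers over 2 chromosomes in small_cfg
    spacing = 50_000_000 / per_chrom
    return int((int(idx) - 0.5) * spacing)


class TestFeatureTrack:
    def _truth(self, cfg, seed=0):
        geno = simulate_genotypes(cfg, seed)
        _, truth = simulate_annotation(cfg, geno, seed + 1)
        return truth

    def test_homogeneous_rates_no_inside_outside_difference(self):
        cfg = small_cfg(feature_rate_in=5.0, feature_rate_out=5.0)
        truth = self._truth(cfg)
        inside_d, outside_d = [], []
        for s in range(50):
            track = simulate_feature_track(truth, cfg.chrom_sizes, cfg, seed=s)
            n_in = length_in = 0
            for c in truth.planted_clusters:
                lo = max(0, c.span.start - cfg.feature_flank_bp)
                hi = min(cfg.chrom_length_bp, c.span.end + cfg.feature_flank_bp)
                region = ec.GenomicRegion(c.chrom, lo, hi)
                n_in += ec.count_features_in_region(region, track)
                length_in += region.length
            genome_mb = sum(cfg.chrom_sizes.values()) / 1e6
            inside_d.append(n_in / (length_in / 1e6))
            outside_d.append((len(track) - n_in) / (genome_mb - length_in / 1e6))
        p = stats.ttest_rel(inside_d, outside_d).pvalue
        assert p > 0.01

    def test_zero_outside_rate(self):
        cfg = small_cfg(feature_rate_in=10.0, feature_rate_out=0.0)
        truth = self._truth(cfg)
        track = simulate_feature_track(truth, cfg.chrom_sizes, cfg, seed=3)
        spans = [
            ec.GenomicRegion(
                c.chrom,
                max(0, c.span.start - cfg.feature_flank_bp),
                c.span.end + cfg.feature_flank_bp,
            )
            for c in truth.planted_clusters
        ]
        for r in track.regions():
            assert any(r.overlaps(s) for s in spans)

    def test_poisson_mean_inside_spans(self):
        # rate 10/Mb over 1 Mb inside intervals (span 0.5 Mb + 0.25 Mb
        # flanks) -> per-span counts ~ Poisson(10); the 500-sim mean
        # must fall in the 99% CI of the mean of 500*k Poisson draws.
        cfg = small_cfg(
            cluster_span_bp=500_000,
            feature_flank_bp=250_000,
            feature_rate_in=10.0,
            feature_rate_out=0.0,
            n_planted_clusters=4,
        )
        truth = self._truth(cfg)
        counts = []
        rng = np.random.default_rng(99)
        for _ in range(500):
            track = simulate_feature_track(truth, cfg.chrom_sizes, cfg, seed=rng)
            for c in truth.planted_clusters:
                region = ec.GenomicRegion(
                    c.chrom,
                    max(0, c.span.start - cfg.feature_flank_bp),
                    c.span.end + cfg.feature_flank_bp,
                )
                counts.append(ec.count_features_in_region(region, track))
        mean_expected = 10.0
        se = np.sqrt(mean_expected / len(counts))
        z = abs(np.mean(counts) - mean_expected) / se
        assert z < 2.576  # 99% normal CI

    def test_rate_invariant_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(feature_rate_in=1.0, feature_rate_out=2.0)


class TestBundle:
    def test_deterministic_given_seed(self):
        a = simulate_bundle(SimConfig(n_genes=300, n_markers=200, n_chrom=2), seed=9)
        b = simulate_bundle(SimConfig(n_genes=300, n_markers=200, n_chrom=2), seed=9)
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(
            a.tracks["sine_polymorphic"].df, b.tracks["sine_polymorphic"].df
        )
        assert a.truth.planted_clusters == b.truth.planted_clusters

    def test_bundle_round_trip_through_files(self, tmp_path):
        bundle = simulate_bundle(SimConfig(n_genes=200, n_markers=100, n_chrom=2), seed=4)
        paths = ec.write_bundle(bundle, tmp_path)
        geno, expr, ann, sizes, tracks = ec.load_inputs(
            paths["genotypes"],
            paths["expression"],
            paths["annotation"],
            paths["detection"],
            paths["chrom_sizes"],
            {
                "sine_polymorphic": paths["track_sine_polymorphic"],
                "sine_fixed": paths["track_sine_fixed"],
            },
        )
        np.testing.assert_array_equal(geno.calls, bundle.genotypes.calls)
        assert expr.detection is not None
        np.testing.assert_allclose(
            expr.values.to_numpy(), bundle.expression.values.to_numpy(), atol=1e-6
        )
        assert sizes == bundle.chrom_sizes
        assert len(tracks["sine_polymorphic"]) == len(bundle.tracks["sine_polymorphic"])
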
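"""Max-gap clustering, null region construction, haplotype blocks,
adjacent-marker LD and cluster heterogeneity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import eqtlclust as ec
from eqtlclust.clusters import (
    adjacent_marker_ld,
    augment_flanks,
    build_control_clusters,
    cluster_heterogeneity,
    detect_clusters,
    haplotype_blocks,
    sample_random_regions,
    single_eqtl_regions,
)
from eqtlclust.types import (
    Cluster,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicRegion,
    GenotypeMatrix,
    Marker,
)


def positions_frame(starts, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
        }
    )


def brute_force_runs(starts: list[int], max_gap: int, min_size: int):
    """O(n^2) oracle: every (i, j) index pair is checked for being a
    valid maximal run of the sorted positions."""
    s = sorted(starts)
    runs = []
    n = len(s)
    for i in range(n):
        for j in range(i, n):
            ok = all(s[k + 1] - s[k] <= max_gap for k in range(i, j))
            left_maximal = i == 0 or s[i] - s[i - 1] > max_gap
            right_maximal = j == n - 1 or s[j + 1] - s[j] > max_gap
            if ok and left_maximal and right_maximal and j - i + 1 >= min_size:
                runs.append((s[i], s[j], j - i + 1))
    return runs


class TestDetectClusters:
    def test_three_genes_within_gap(self):
        found = detect_clusters(positions_frame([0, 200_000, 400_000]), 250_000, 3)
        assert len(found) == 1
        c = found[0]
        assert c.n_members == 3
        assert (c.span.start, c.span.end) == (0, 400_000)

    def test_all_gaps_exceeded(self):
        found = detect_clusters(positions_frame([0, 300_000, 600_000]), 250_000, 3)
        assert found == []

    @settings(deadline=None, max_examples=60)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(0, 20),
        gap=st.sampled_from([250_000, 500_000, 750_000]),
    )
    def test_matches_brute_force(self, seed, n, gap):
        rng = np.random.default_rng(seed)
        starts = rng.choice(5_000_000, size=n, replace=False).tolist()
        found = detect_clusters(positions_frame(starts), gap, 3)
        got = sorted((c.span.start, max(m for m in _starts(c)), c.n_members) for c in found)
        assert got == sorted(brute_force_runs(starts, gap, 3))

    def test_input_order_invariance_and_idempotence(self):
        rng = np.random.default_rng(3)
        starts = rng.choice(3_000_000, size=15, replace=False).tolist()
        a = detect_clusters(positions_frame(starts), 250_000, 3)
        df = positions_frame(starts).sample(frac=1, random_state=1)
        b = detect_clusters(df, 250_000, 3)
        assert [c.span for c in a] == [c.span for c in b]
        assert [set(c.members) for c in a] == [set(c.members) for c in b]

    def test_union_of_clusters_and_singletons_is_input(self):
        rng = np.random.default_rng(4)
        starts = rng.choice(2_000_000, size=12, replace=False).tolist()
        frame = positions_frame(starts)
        found = detect_clusters(frame, 250_000, 3)
        members = {g for c in found for g in c.members}
        singles = set(frame["gene_id"]) - members
        assert members | singles == set(frame["gene_id"])
        assert members & singles == set()


def _starts(cluster):
    # member gene ids are g{i} over the original frame; recover the
    # span endpoints from the cluster record itself
    return (cluster.span.start, cluster.span.end)


class TestControlClusters:
    def test_full_overlap_gives_zero_controls(self):
        frame = positions_frame([0, 100_000, 200_000])
        cis = detect_clusters(frame, 250_000, 3, kind="cis")
        controls, report = build_control_clusters(frame, cis, 250_000, 3)
        assert controls == []

    def test_span_cap_drops_candidates(self):
        detected = positions_frame([0, 200_000, 400_000, 3_000_000, 3_200_000, 3_400_000])
        cis = [
            Cluster("cis", "chr1", GenomicRegion("chr1", 10_000_000, 10_100_000), ("x",), 250_000)
        ]
        controls, _ = build_control_clusters(
            detected, cis, 250_000, 3, max_span_bp=300_000
        )
        assert controls == []  # both candidate spans are 400 kb > cap

    def test_no_control_overlaps_cis_span(self, default_bundle):
        _, result = default_bundle
        for ctrl in result.control_clusters:
            for cis in result.cis_clusters:
                assert not ctrl.span.overlaps(cis.span)

    def test_span_match_on_default_bundle(self, default_bundle):
        _, result = default_bundle
        assert result.control_report["span_p"] > 0.05

    def test_mismatch_warns(self):
        detected = positions_frame(
            list(range(0, 1_000_000, 100_000))
            + list(range(10_000_000, 11_000_000, 100_000))
        )
        cis = [
            Cluster(
                "cis",
                "chr2",
                GenomicRegion("chr2", off, off + 10_000),
                ("a", "b", "c"),
                250_000,
            )
            for off in (0, 50_000_000, 90_000_000)
        ]
        with pytest.warns(UserWarning, match="differ"):
            build_control_clusters(detected, cis, 250_000, 3, max_span_bp=10**9)


class TestRandomRegions:
    def test_uniform_placement(self):
        regions = sample_random_regions({"chr1": 10_000_000}, [1_000_000], 2000, rng=0)
        starts = [c.span.start for c in regions]
        p = stats.kstest(starts, stats.uniform(loc=0, scale=9_000_000).cdf).pvalue
        assert p > 0.01

    def test_forced_into_only_slot(self):
        exclusions = [
            GenomicRegion("chr1", 0, 4_000_000),
            GenomicRegion("chr1", 5_000_000, 10_000_000),
        ]
        regions = sample_random_regions(
            {"chr1": 10_000_000}, [900_000], 20, exclusions, rng=1
        )
        for c in regions:
            assert 4_000_000 <= c.span.start and c.span.end <= 5_000_000

    def test_deterministic_under_seed(self):
        a = sample_random_regions({"chr1": 10**7, "chr2": 2 * 10**7}, [10**6], 50, rng=7)
        b = sample_random_regions({"chr1": 10**7, "chr2": 2 * 10**7}, [10**6], 50, rng=7)
        assert [c.span for c in a] == [c.span for c in b]

    def test_impossible_exclusions_error(self):
        exclusions = [GenomicRegion("chr1", 0, 10_000_000)]
        with pytest.raises(RuntimeError, match="rejection rate"):
            sample_random_regions({"chr1": 10_000_000}, [1_000_000], 5, exclusions, rng=2)

    def test_size_larger_than_genome_error(self):
        with pytest.raises(ValueError, match="exceeds every chromosome"):
            sample_random_regions({"chr1": 10_000}, [1_000_000], 1, rng=0)


class TestFlanksAndSingles:
    def test_flank_arithmetic(self):
        r = augment_flanks(GenomicRegion("chr1", 1_000_000, 1_200_000), 250_000, 10**8)
        assert (r.start, r.end) == (750_000, 1_450_000)

    def test_flank_clipped_at_chromosome_start(self):
        r = augment_flanks(GenomicRegion("chr1", 100_000, 200_000), 500_000, 10**8)
        assert r.start == 0

    def test_zero_flank_identity(self):
        region = GenomicRegion("chr1", 5, 10)
        assert augment_flanks(region, 0, 100) == region

    def test_single_region_centering(self):
        singles = single_eqtl_regions(
            positions_frame([5_000_000]), 1_000_000, {"chr1": 10**8}
        )
        assert (singles[0].span.start, singles[0].span.end) == (4_500_000, 5_500_000)

    def test_single_region_clipped(self):
        singles = single_eqtl_regions(
            positions_frame([100_000]), 1_000_000, {"chr1": 10**8}
        )
        assert (singles[0].span.start, singles[0].span.end) == (0, 600_000)

    def test_single_count_is_set_difference(self, default_bundle):
        _, result = default_bundle
        cis_genes = set(result.eqtls.loc[result.eqtls["kind"] == "cis", "gene_id"])
        members = {g for c in result.cis_clusters for g in c.members}
        assert len(result.single_regions) == len(cis_genes - members)


def geno_from_calls(calls, positions=None, chrom="chr1"):
    calls = np.asarray(calls, dtype=float)
    n_markers = calls.shape[1]
    positions = positions or [1_000_000 * (j + 1) for j in range(n_markers)]
    markers = [Marker(f"m{j}", chrom, positions[j]) for j in range(n_markers)]
    return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], markers, calls)


class TestHaplotypeBlocks:
    def test_definitional(self):
        geno = geno_from_calls(
            np.array([[0, 0, 0], [1, 1, 1]]), [1_000_000, 4_000_000, 9_000_000]
        )
        blocks = haplotype_blocks(geno)
        assert [(b.start, b.end) for b in blocks] == [
            (1_000_000, 4_000_000),
            (4_000_000, 9_000_000),
        ]

    def test_single_marker_chromosome_warns(self):
        geno = geno_from_calls(np.array([[0], [1]]))
        with pytest.warns(UserWarning, match="<2 informative"):
            assert haplotype_blocks(geno) == []

    def test_count_is_k_minus_one_per_chromosome(self):
        rng = np.random.default_rng(0)
        blocks_total = 0
        expected = 0
        for chrom, k in (("chr1", 7), ("chr2", 4)):
            calls = rng.integers(0, 2, size=(10, k)).astype(float)
            # force informativeness
            calls[0] = 0
            calls[1] = 1
            geno = geno_from_calls(calls, chrom=chrom)
            blocks = haplotype_blocks(geno)
            assert all(b.chrom == chrom for b in blocks)
            blocks_total += len(blocks)
            expected += k - 1
        assert blocks_total == expected

    def test_no_informative_marker_inside_block(self, default_bundle):
        bundle, _ = default_bundle
        blocks = haplotype_blocks(bundle.genotypes)
        informative = {
            (m.chrom, m.pos) for m in bundle.genotypes.informative()
        }
        for b in blocks:
            interior = [
                p for c, p in informative if c == b.chrom and b.start < p < b.end
            ]
            assert interior == []


class TestAdjacentMarkerLd:
    def test_identical_vectors_r2_one(self):
        calls = np.array([[0, 0], [1, 1], [0, 0], [1, 1]])
        ld = adjacent_marker_ld(geno_from_calls(calls))
        assert ld["r2"].iloc[0] == pytest.approx(1.0)

    def test_balanced_complementary_halves_r2_zero(self):
        calls = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        ld = adjacent_marker_ld(geno_from_calls(calls))
        assert ld["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_correlation(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, size=(24, 10)).astype(float)
        calls[0] = 0
        calls[1] = 1
        geno = geno_from_calls(calls)
        ld = adjacent_marker_ld(geno)
        for row in ld.itertuples():
            a = geno.column(row.marker_a)
            b = geno.column(row.marker_b)
            expected = np.corrcoef(a, b)[0, 1] ** 2
            assert abs(row.r2 - expected) < 1e-12


class TestHeterogeneity:
    def _cluster(self, genes):
        return Cluster("cis", "chr1", GenomicRegion("chr1", 0, 100), tuple(genes))

    def _annotation(self, strands):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(len(strands)),
                "strand": strands,
            },
            index=[f"g{i}" for i in range(len(strands))],
        )
        return GeneAnnotation(df)

    def test_all_positive_correlations_consistent(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=24)
        values = pd.DataFrame(
            [base + rng.normal(0, 0.1, 24) for _ in range(3)],
            index=["g0", "g1", "g2"],
            columns=[f"s{i}" for i in range(24)],
        )
        expr = ExpressionMatrix(values)
        consistent, both = cluster_heterogeneity(
            self._cluster(["g0", "g1", "g2"]), expr, self._annotation(["+", "+", "-"])
        )
        assert consistent is True
        assert both is True

    def test_sign_flip_breaks_consistency(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=24)
        values = pd.DataFrame(
            [base, base, -base],
            index=["g0", "g1", "g2"],
            columns=[f"s{i}" for i in range(24)],
        )
        consistent, _ = cluster_heterogeneity(
            self._cluster(["g0", "g1", "g2"]),
            ExpressionMatrix(values),
            self._annotation(["+", "+", "+"]),
        )
        assert consistent is False

    def test_missing_strand_gives_none(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.normal(size=(2, 24)),
            index=["g0", "g1"],
            columns=[f"s{i}" for i in range(24)],
        )
        df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1], "strand": ["+", "?"]},
            index=["g0", "g1"],
        )
        _, both = cluster_heterogeneity(
            self._cluster(["g0", "g1"]), ExpressionMatrix(values), GeneAnnotation(df)
        )
        assert both is None

    def test_random_sign_consistency_frequency(self):
        # 4 members with random per-gene signs on a dominant shared
        # factor: all-pairwise-positive happens iff all signs agree,
        # probability 2 * (1/2)^4 = 1/8
        rng = np.random.default_rng(5)
        hits = 0
        n_sim = 1000
        ann = self._annotation(["+"] * 4)
        for _ in range(n_sim):
            factor = rng.normal(size=24)
            signs = rng.choice([-1, 1], size=4)
            values = pd.DataFrame(
                [s * factor + rng.normal(0, 0.05, 24) for s in signs],
                index=[f"g{i}" for i in range(4)],
                columns=[f"s{i}" for i in range(24)],
            )
            consistent, _ = cluster_heterogeneity(
                self._cluster([f"g{i}" for i in range(4)]), ExpressionMatrix(values), ann
            )
            hits += consistent
        lo, hi = stats.binom.interval(0.999, n_sim, 1 / 8)
        assert lo <= hits <= hi
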
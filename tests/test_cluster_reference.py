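import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnapipe.cluster_reference import (
    ReferenceFilterParams,
    count_reads_per_cluster,
    filter_reference,
    merge_alignments,
    merge_intervals,
    nearest_gene,
)
from pirnapipe.core_io import (
    AlignmentRecord,
    ClusterSet,
    CollapsedRead,
    GenomicInterval,
)

from conftest import brute_force_merge


def _aln(scaffold, start, length=30, count=1, strand="+"):
    return AlignmentRecord(
        CollapsedRead("A" * length, count),
        GenomicInterval(scaffold, start, start + length, strand),
    )


def _intervals(spec):
    return [GenomicInterval(s, a, b) for s, a, b in spec]


class TestMergeIntervals:
    def test_gap_at_distance_merges(self):
        merged = merge_intervals(_intervals([("s1", 100, 130), ("s1", 1120, 1150)]), 1000)
        assert [(m.start, m.end) for m in merged] == [(100, 1150)]

    def test_gap_beyond_distance_splits(self):
        merged = merge_intervals(_intervals([("s1", 100, 130), ("s1", 1131, 1160)]), 1000)
        assert [(m.start, m.end) for m in merged] == [(100, 130), (1131, 1160)]

    def test_bookended_always_merge(self):
        merged = merge_intervals(_intervals([("s1", 0, 50), ("s1", 50, 80)]), 0)
        assert [(m.start, m.end) for m in merged] == [(0, 80)]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals(_intervals([("s1", 0, 10)]), -1)

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(50):
            ivs = []
            for _ in range(int(rng.integers(2, 200))):
                scaffold = f"s{int(rng.integers(1, 4))}"
                start = int(rng.integers(0, 20_000))
                ivs.append(GenomicInterval(scaffold, start, start + int(rng.integers(1, 400))))
            d = int(rng.integers(0, 1_500))
            got = [(m.scaffold, m.start, m.end) for m in merge_intervals(ivs, d)]
            assert sorted(got) == brute_force_merge(ivs, d)

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 200)), min_size=1, max_size=50
        ),
        st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_monotone(self, raw, d):
        ivs = [GenomicInterval("s", a, a + w) for a, w in raw]
        once = merge_intervals(ivs, d)
        assert merge_intervals(once, d) == once
        # a larger distance can only reduce the number of clusters
        assert len(merge_intervals(ivs, d + 500)) <= len(once)

    def test_stranded_merge_keeps_strands_apart(self):
        alns = [_aln("s1", 0, strand="+"), _aln("s1", 100, strand="-")]
        assert len(merge_alignments(alns, 1000, stranded=True)) == 2
        assert len(merge_alignments(alns, 1000, stranded=False)) == 1


class TestCountReads:
    CLUSTERS = ClusterSet([GenomicInterval("s1", 0, 100), GenomicInterval("s1", 500, 600)])

    def test_single_placement_adds_count(self):
        counts, out = count_reads_per_cluster([_aln("s1", 10, count=7)], self.CLUSTERS)
        assert counts["s1:0-100"] == 7 and out == 0

    def test_multi_placement_counted_per_site(self):
        read = CollapsedRead("A" * 30, 4)
        alns = [
            AlignmentRecord(read, GenomicInterval("s1", 10, 40, "+")),
            AlignmentRecord(read, GenomicInterval("s1", 510, 540, "+")),
        ]
        counts, _ = count_reads_per_cluster(alns, self.CLUSTERS)
        assert counts["s1:0-100"] == 4 and counts["s1:500-600"] == 4
        frac, _ = count_reads_per_cluster(alns, self.CLUSTERS, count_mode="fractional")
        assert frac["s1:0-100"] == 2 and frac["s1:500-600"] == 2

    def test_conservation_of_counts(self, rng):
        alns = [
            _aln("s1", int(rng.integers(0, 900)), count=int(rng.integers(1, 9)))
            for _ in range(50)
        ]
        counts, unassigned = count_reads_per_cluster(alns, self.CLUSTERS)
        total_in = sum(
            a.read.count
            * sum(1 for c in self.CLUSTERS if c.overlaps(a.interval))
            for a in alns
        )
        total_out = sum(a.read.count for a in alns if not any(
            c.overlaps(a.interval) for c in self.CLUSTERS))
        assert sum(counts.values()) == total_in and unassigned == total_out


class TestFilterReference:
    PRELIM = ClusterSet([GenomicInterval("s1", 0, 100)])

    def _keep(self, ox, testis, **kw):
        params = ReferenceFilterParams(**kw) if kw else None
        final = filter_reference(
            self.PRELIM, {"s1:0-100": ox}, {"s1:0-100": testis}, params
        )
        return len(final) == 1

    def test_both_below_floor_excluded(self):
        assert not self._keep(9, 9)

    def test_low_oxidation_ratio_excluded(self):
        assert not self._keep(5, 100)

    def test_zero_testis_ratio_infinite_retained(self):
        assert self._keep(50, 0)

    def test_zero_ox_with_expressed_testis_excluded(self):
        assert not self._keep(0, 100)

    def test_missing_counts_error(self):
        with pytest.raises(ValueError, match="missing"):
            filter_reference(self.PRELIM, {}, {"s1:0-100": 5})

    def test_monotone_in_thresholds(self):
        # raising min_count or min_ox_ratio never adds clusters
        ivs = ClusterSet([GenomicInterval("s1", i * 1000, i * 1000 + 100) for i in range(30)])
        rng = np.random.default_rng(7)
        ox = {c.id: int(rng.integers(0, 80)) for c in ivs}
        te = {c.id: int(rng.integers(0, 80)) for c in ivs}
        sizes = [
            len(filter_reference(ivs, ox, te, ReferenceFilterParams(1000, mc, mr)))
            for mc, mr in [(5, 0.05), (10, 0.05), (10, 0.1), (20, 0.3)]
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestNearestGene:
    def test_overlapping_gene_distance_zero(self):
        clusters = ClusterSet([GenomicInterval("s1", 100, 200)])
        genes = [GenomicInterval("s1", 150, 400)]
        gid, dist, near = nearest_gene(clusters, genes)["s1:100-200"]
        assert dist == 0 and near

    def test_downstream_distance_and_flag(self):
        clusters = ClusterSet([GenomicInterval("s1", 500, 1000)])
        genes = [GenomicInterval("s1", 5000, 5500)]
        gid, dist, near = nearest_gene(clusters, genes)["s1:500-1000"]
        assert dist == 4000 and near

    def test_beyond_10kb_not_flagged(self):
        clusters = ClusterSet([GenomicInterval("s1", 0, 100)])
        genes = [GenomicInterval("s1", 20_000, 21_000)]
        _, dist, near = nearest_gene(clusters, genes)["s1:0-100"]
        assert dist == 19_900 and not near

    def test_agrees_with_bruteforce_minimum(self, rng):
        clusters = ClusterSet(
            [GenomicInterval("s1", int(p), int(p) + 50) for p in range(0, 30_000, 3_000)]
        )
        genes = []
        for _ in range(40):
            start = int(rng.integers(0, 30_000))
            genes.append(GenomicInterval("s1", start, start + int(rng.integers(50, 900))))
        result = nearest_gene(clusters, genes)
        for c in clusters:
            def dist(g):
                if g.start < c.end and c.start < g.end:
                    return 0
                return g.start - c.end if g.start >= c.end else c.start - g.end
            best = min(dist(g) for g in genes)
            assert abs(result[c.id][1]) == best
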
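import numpy as np
import pytest

from pirnapipe.core_io import (
    AlignmentRecord,
    CollapsedRead,
    GenomicInterval,
    RepeatInterval,
    reverse_complement,
)
from pirnapipe.prefilter import (
    FilterReport,
    exclude_by_repeat_mask,
    exclude_by_sequence_set,
    length_filter,
    low_abundance_filter,
    prefilter_reads,
)

from conftest import make_read


def _aln(seq, scaffold, start, strand="+"):
    return AlignmentRecord(
        CollapsedRead(seq, 1), GenomicInterval(scaffold, start, start + len(seq), strand)
    )


class TestLengthFilter:
    def test_inclusive_boundaries(self):
        reads = [make_read("A" * n) for n in (24, 25, 32, 33)]
        kept = length_filter(reads)
        assert [len(r.sequence) for r in kept] == [25, 32]

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_window_passes_everything_inside(self):
        reads = [make_read("C" * 28) for _ in range(5)]
        assert length_filter(reads) == reads

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            length_filter([], min_len=30, max_len=25)


class TestSequenceSetExclusion:
    HAIRPIN = "ACGTACGGTTCAGCTACGATCGATTACGGATCAGGCTACGGCTAGCTAACGTACGATCAG"

    def test_window_of_reference_removed(self):
        read = make_read(self.HAIRPIN[10:38])
        assert exclude_by_sequence_set([read], [self.HAIRPIN]) == []

    def test_reverse_complement_window_removed(self):
        read = make_read(reverse_complement(self.HAIRPIN[5:33]))
        assert exclude_by_sequence_set([read], [self.HAIRPIN]) == []

    def test_one_mismatch_kept_matches_bruteforce(self, rng):
        # mutate one base of a window; verify agreement with an all-window scan
        refs = ["".join(rng.choice(list("ACGT"), size=70)) for _ in range(5)]
        reads = []
        for _ in range(30):
            ref = refs[int(rng.integers(5))]
            off = int(rng.integers(0, len(ref) - 28))
            window = list(ref[off : off + 28])
            if rng.random() < 0.5:  # half get a single mutation
                i = int(rng.integers(28))
                window[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[i]]
            reads.append(make_read("".join(window)))
        kept = exclude_by_sequence_set(reads, refs)

        def brute_hit(seq):
            for q in (seq, reverse_complement(seq)):
                for ref in refs:
                    for i in range(len(ref) - len(q) + 1):
                        if ref[i : i + len(q)] == q:
                            return True
            return False

        assert kept == [r for r in reads if not brute_hit(r.sequence)]

    def test_exact_mode_only_full_matches(self):
        read = make_read(self.HAIRPIN[10:38])
        assert exclude_by_sequence_set([read], [self.HAIRPIN], mode="exact") == [read]
        assert exclude_by_sequence_set([read], [read.sequence], mode="exact") == []

    def test_hamming_option_removes_near_matches(self):
        window = self.HAIRPIN[10:38]
        mutated = "G" + window[1:] if window[0] != "G" else "A" + window[1:]
        read = make_read(mutated)
        assert exclude_by_sequence_set([read], [self.HAIRPIN]) == [read]
        assert exclude_by_sequence_set([read], [self.HAIRPIN], max_mismatches=1) == []

    def test_empty_reference_warns_and_keeps(self):
        reads = [make_read("A" * 28)]
        with pytest.warns(UserWarning):
            assert exclude_by_sequence_set(reads, []) == reads


class TestRepeatMaskExclusion:
    MASK = [
        RepeatInterval(GenomicInterval("s1", 100, 200), "Simple_repeat"),
        RepeatInterval(GenomicInterval("s1", 500, 800), "LTR"),
        RepeatInterval(GenomicInterval("s1", 1000, 1100), "tRNA"),
    ]

    def test_simple_repeat_overlap_removed(self):
        assert exclude_by_repeat_mask([_aln("A" * 28, "s1", 150)], self.MASK) == []

    def test_ltr_overlap_kept(self):
        alns = [_aln("A" * 28, "s1", 600)]
        assert exclude_by_repeat_mask(alns, self.MASK) == alns

    def test_single_bp_overlap_removed(self):
        # read ends at 101, mask starts at 100: 1 bp overlap suffices
        assert exclude_by_repeat_mask([_aln("A" * 28, "s1", 73)], self.MASK) == []
        # book-ended (no overlap) is kept
        alns = [_aln("A" * 28, "s1", 72)]
        assert exclude_by_repeat_mask(alns, self.MASK) == alns

    def test_unknown_class_retained_with_warning(self):
        mask = [RepeatInterval(GenomicInterval("s1", 100, 200), "Mystery")]
        alns = [_aln("A" * 28, "s1", 150)]
        with pytest.warns(UserWarning, match="Mystery"):
            assert exclude_by_repeat_mask(alns, mask) == alns


class TestLowAbundance:
    def test_count_boundary(self):
        reads = [make_read("A" * 28, 9), make_read("C" * 28, 10)]
        assert low_abundance_filter(reads) == [reads[1]]

    def test_min_count_one_keeps_all(self):
        reads = [make_read("A" * 28, 1)]
        assert low_abundance_filter(reads, min_count=1) == reads

    def test_invalid_min_count(self):
        with pytest.raises(ValueError):
            low_abundance_filter([], min_count=0)

    def test_removed_fraction_of_lognormal_mixture(self, rng):
        # counts from a discretized lognormal calibrated so ~28 % of unique
        # sequences fall below 10 reads; removal fraction equals a direct count
        counts = np.maximum(1, np.round(np.exp(rng.normal(3.05, 1.4, 5000)))).astype(int)
        reads = [make_read(f"{'A' * 20}{i:08b}".replace("0", "C").replace("1", "G"), int(c))
                 for i, c in enumerate(counts)]
        kept = low_abundance_filter(reads, min_count=10)
        removed_fraction = 1 - len(kept) / len(reads)
        assert removed_fraction == np.mean(counts < 10)
        assert removed_fraction == pytest.approx(0.28, abs=0.03)


class TestCascade:
    def test_accounting_balances_and_is_idempotent(self, rng):
        mirna = {"m1": "".join(rng.choice(list("ACGT"), size=80))}
        trna = {"t1": "".join(rng.choice(list("ACGT"), size=75))}
        reads = [make_read("".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 36)))),
                           int(rng.integers(1, 40))) for _ in range(200)]
        reads += [make_read(mirna["m1"][3:31], 5), make_read(trna["t1"][10:38], 50)]

        report = FilterReport()
        out = prefilter_reads(reads, mirna, trna, min_count=10, report=report)
        report.validate()
        assert report.input_unique - report.output_unique == sum(
            s.unique_removed for s in report.stages
        )
        again = prefilter_reads(out, mirna, trna, min_count=10)
        assert again == out

    def test_stage_order_length_first(self):
        # a 20-nt miRNA window is removed by length, not attributed to miRNA
        mirna = {"m1": "ACGTACGTACGTACGTACGTACGTACGT"}
        report = FilterReport()
        prefilter_reads([make_read(mirna["m1"][:20])], mirna, report=report)
        stages = {s.name: s.unique_removed for s in report.stages}
        assert stages["length"] == 1 and stages["mirna"] == 0
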
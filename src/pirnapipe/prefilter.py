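"""Read-level exclusion cascade applied to each sample before mapping.

Order is length -> miRNA -> tRNA -> repeat mask -> low abundance. The
length window (25-32 nt inclusive) selects the piRNA size class; miRNA and
tRNA exclusion removes reads matching known contaminant sequences; the
repeat-mask step (applied to mapped positions) removes leftover tRNA/rRNA/
simple-repeat placements while retaining TE-derived ones; the low-abundance
floor (count >= 10) is applied to oxidized samples before reference
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .core_io import (
    AlignmentRecord,
    CollapsedRead,
    RepeatInterval,
    reverse_complement,
)

# RepeatMasker classes excluded vs retained, following the rule that leftover
# structural/simple repeats go but TE-derived ncRNA placements stay.
EXCLUDED_REPEAT_CLASSES = frozenset(
    {"tRNA", "rRNA", "Simple_repeat", "Low_complexity"}
)
RETAINED_REPEAT_CLASSES = frozenset({"LTR", "LINE", "SINE", "DNA", "RC"})


@dataclass
class FilterStage:
    name: str
    unique_removed: int = 0
    reads_removed: int = 0


@dataclass
class FilterReport:
    """Per-stage accounting of unique sequences and total reads removed."""

    input_unique: int = 0
    input_reads: int = 0
    output_unique: int = 0
    output_reads: int = 0
    stages: list[FilterStage] = field(default_factory=list)

    def add_stage(self, name: str, before: Sequence, after: Sequence) -> None:
        self.stages.append(
            FilterStage(
                name,
                unique_removed=len(before) - len(after),
                reads_removed=_total(before) - _total(after),
            )
        )

    def validate(self) -> None:
        if sum(s.unique_removed for s in self.stages) != (
            self.input_unique - self.output_unique
        ):
            raise AssertionError("unique-sequence accounting does not balance")
        if sum(s.reads_removed for s in self.stages) != (
            self.input_reads - self.output_reads
        ):
            raise AssertionError("read accounting does not balance")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tunique_removed\treads_removed\n")
            for s in self.stages:
                fh.write(f"{s.name}\t{s.unique_removed}\t{s.reads_removed}\n")
            fh.write(f"input\t{self.input_unique}\t{self.input_reads}\n")
            fh.write(f"output\t{self.output_unique}\t{self.output_reads}\n")


def _total(reads: Sequence[CollapsedRead]) -> int:
    return sum(r.count for r in reads)


def length_filter(
    reads: Sequence[CollapsedRead], min_len: int = 25, max_len: int = 32
) -> list[CollapsedRead]:
    """Keep reads with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def exclude_by_sequence_set(
    reads: Sequence[CollapsedRead],
    reference_seqs: Mapping[str, str] | Iterable[str],
    mode: str = "substring",
    max_mismatches: int = 0,
) -> list[CollapsedRead]:
    """Remove reads hitting a known-sequence set (miRNA hairpins, tRNAs).

    A read is removed iff its sequence, or its reverse complement, occurs as
    an exact substring of any reference sequence (``mode="substring"``, the
    default) or equals a reference exactly (``mode="exact"``). Mismatch
    tolerance (Hamming distance <= ``max_mismatches`` against every window)
    is available but off by default.
    """
    if mode not in ("substring", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    refs = (
        list(reference_seqs.values())
        if isinstance(reference_seqs, Mapping)
        else list(reference_seqs)
    )
    if not refs:
        warnings.warn("empty reference sequence set: no reads excluded")
        return list(reads)

    if mode == "exact":
        ref_set = set(refs)
        return [
            r
            for r in reads
            if r.sequence not in ref_set
            and reverse_complement(r.sequence) not in ref_set
        ]

    if max_mismatches == 0:
        joined = "\n".join(refs)  # newline never matches a base
        return [
            r
            for r in reads
            if r.sequence not in joined
            and reverse_complement(r.sequence) not in joined
        ]

    kept = []
    for r in reads:
        if not _hamming_hit(r.sequence, refs, max_mismatches) and not _hamming_hit(
            reverse_complement(r.sequence), refs, max_mismatches
        ):
            kept.append(r)
    return kept


def _hamming_hit(seq: str, refs: list[str], max_mm: int) -> bool:
    k = len(seq)
    for ref in refs:
        for i in range(len(ref) - k + 1):
            window = ref[i : i + k]
            mm = 0
            for a, b in zip(seq, window):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                return True
    return False


def exclude_by_repeat_mask(
    alignments: Sequence[AlignmentRecord],
    mask: Sequence[RepeatInterval],
    excluded_classes: frozenset[str] | set[str] = EXCLUDED_REPEAT_CLASSES,
) -> list[AlignmentRecord]:
    """Drop alignments overlapping (>= 1 bp) masked intervals of excluded classes.

    TE-class intervals (LTR/LINE/SINE/DNA/RC) are retained; an unknown class
    string is retained with a warning (conservative).
    """
    trees: dict[str, IntervalTree] = {}
    warned: set[str] = set()
    for rep in mask:
        rclass = rep.repeat_class
        if rclass in excluded_classes:
            trees.setdefault(rep.interval.scaffold, IntervalTree()).addi(
                rep.interval.start, rep.interval.end
            )
        elif rclass not in RETAINED_REPEAT_CLASSES and rclass not in warned:
            warnings.warn(f"unknown repeat class {rclass!r}: retained")
            warned.add(rclass)

    kept = []
    for aln in alignments:
        tree = trees.get(aln.interval.scaffold)
        if tree is None or not tree.overlap(aln.interval.start, aln.interval.end):
            kept.append(aln)
    return kept


def low_abundance_filter(
    reads: Sequence[CollapsedRead], min_count: int = 10
) -> list[CollapsedRead]:
    """Keep reads with count >= min_count (default removes counts below 10)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [r for r in reads if r.count >= min_count]


def prefilter_reads(
    reads: Sequence[CollapsedRead],
    mirna_seqs: Mapping[str, str] | None = None,
    trna_seqs: Mapping[str, str] | None = None,
    min_len: int = 25,
    max_len: int = 32,
    min_count: int | None = None,
    report: FilterReport | None = None,
) -> list[CollapsedRead]:
    """Run the sequence-level cascade: length -> miRNA -> tRNA -> abundance.

    ``min_count`` is applied only when given (oxidized samples before
    reference construction). Repeat-mask exclusion operates on mapped
    positions and is applied separately after mapping.
    """
    if report is None:
        report = FilterReport()
    report.input_unique = len(reads)
    report.input_reads = _total(reads)

    out = length_filter(reads, min_len, max_len)
    report.add_stage("length", reads, out)

    if mirna_seqs is not None:
        prev, out = out, exclude_by_sequence_set(out, mirna_seqs)
        report.add_stage("mirna", prev, out)
    if trna_seqs is not None:
        prev, out = out, exclude_by_sequence_set(out, trna_seqs)
        report.add_stage("trna", prev, out)
    if min_count is not None:
        prev, out = out, low_abundance_filter(out, min_count)
        report.add_stage("low_abundance", prev, out)

    report.output_unique = len(out)
    report.output_reads = _total(out)
    report.validate()
    return out
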
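"""Exact, all-occurrence placement of short reads on a genome.

Seed-and-verify with a hashed k-mer index: every forward-strand k-mer
(default k = 25, the minimum read length) is stored once per occurrence;
each read is looked up by its first k bases and verified against the genome
by direct string comparison, on both strands. This reproduces
output-all-matches, zero-mismatch short-read mapping exactly for reads of
length >= k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import (
    AlignmentRecord,
    CollapsedRead,
    GenomicInterval,
    reverse_complement,
)

_BASES = frozenset("ACGT")


@dataclass
class GenomeIndex:
    k: int
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])


@dataclass
class MappingReport:
    reads_mapped: int = 0
    reads_unmapped: int = 0
    placements: int = 0


def build_index(genome: Mapping[str, str], k: int = 25) -> GenomeIndex:
    """Index every forward-strand genomic k-mer; k-mers containing N are skipped."""
    if k < 10:
        raise ValueError("k < 10 would produce a pathologically dense index")
    postings: dict[str, list[tuple[str, int]]] = {}
    for scaffold in sorted(genome):
        seq = genome[scaffold]
        # track rightmost non-ACGT position inside the current window
        last_bad = -1
        for i in range(len(seq) - k + 1):
            newest = seq[i + k - 1]
            if newest not in _BASES:
                last_bad = i + k - 1
            if last_bad >= i:
                continue
            postings.setdefault(seq[i : i + k], []).append((scaffold, i))
    return GenomeIndex(k=k, postings=postings)


def map_reads(
    reads: Sequence[CollapsedRead],
    index: GenomeIndex,
    genome: Mapping[str, str],
    max_hits: int | None = None,
    report: MappingReport | None = None,
) -> list[AlignmentRecord]:
    """Report every exact full-length occurrence of each read on both strands.

    Reads with zero hits are dropped (tallied in the report); reads containing
    ambiguous bases never match. A read shorter than the seed length is an
    error. Palindromic placements are reported once per strand.
    """
    too_short = [r.sequence for r in reads if len(r.sequence) < index.k]
    if too_short:
        raise ValueError(
            f"{len(too_short)} reads shorter than seed length {index.k}: "
            + ", ".join(too_short[:5])
        )
    if report is None:
        report = MappingReport()

    out: list[AlignmentRecord] = []
    for read in reads:
        hits: list[tuple[str, int, str]] = []
        if _BASES.issuperset(read.sequence):
            for query, strand in (
                (read.sequence, "+"),
                (reverse_complement(read.sequence), "-"),
            ):
                seed = query[: index.k]
                for scaffold, pos in index.lookup(seed):
                    end = pos + len(query)
                    if genome[scaffold][pos:end] == query:
                        hits.append((scaffold, pos, strand))
        if not hits:
            report.reads_unmapped += 1
            continue
        if max_hits is not None and len(hits) > max_hits:
            hits = hits[:max_hits]
        report.reads_mapped += 1
        report.placements += len(hits)
        n = len(read.sequence)
        out.extend(
            AlignmentRecord(read, GenomicInterval(sc, pos, pos + n, strand))
            for sc, pos, strand in hits
        )
    return out
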
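"""Preliminary cluster construction, per-cluster counting, and the two
reference filters that turn the preliminary set into the final reference.

Mapped piRNA positions separated by at most ``merge_distance`` bp (default
1000, the bedtools ``merge -d 1000`` semantics: book-ended and overlapping
intervals always merge, a gap of exactly d merges) are merged transitively
into clusters. A cluster survives into the final reference unless (a) both
the oxidized-testis and testis counts are below ``min_count``, or (b) the
oxidized/non-oxidized testis count ratio falls below ``min_ox_ratio`` —
the latter flags leftovers of highly abundant non-piRNA RNAs, which are
depleted by periodate oxidation while 2'-O-methylated piRNAs survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .core_io import AlignmentRecord, ClusterSet, GenomicInterval


@dataclass
class ReferenceFilterParams:
    merge_distance: int = 1000
    min_count: int = 10
    min_ox_ratio: float = 0.1
    stranded_merge: bool = False

    def __post_init__(self):
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")
        if self.min_ox_ratio < 0:
            raise ValueError("min_ox_ratio must be >= 0")


def merge_intervals(
    intervals: Sequence[GenomicInterval],
    merge_distance: int = 1000,
    stranded: bool = False,
) -> list[GenomicInterval]:
    """Transitively merge intervals whose gap is <= merge_distance.

    Per scaffold (and per strand when ``stranded``), after sorting by start,
    an interval joins the current cluster when next.start - current.end <=
    merge_distance. Merged spans are emitted unstranded unless ``stranded``.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    keyfn = (
        (lambda iv: (iv.scaffold, iv.strand)) if stranded else (lambda iv: iv.scaffold)
    )
    groups: dict[tuple | str, list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault(keyfn(iv), []).append(iv)

    merged: list[GenomicInterval] = []
    for key in sorted(groups):
        ivs = sorted(groups[key], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strand = ivs[0].strand if stranded else "."
        scaffold = ivs[0].scaffold
        for iv in ivs[1:]:
            if iv.start - cur_end <= merge_distance:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(scaffold, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(scaffold, cur_start, cur_end, strand))
    return sorted(merged, key=lambda iv: (iv.scaffold, iv.start))


def merge_alignments(
    alignments: Sequence[AlignmentRecord],
    merge_distance: int = 1000,
    stranded: bool = False,
) -> ClusterSet:
    """Build the preliminary cluster reference from mapped read positions."""
    if not alignments:
        raise ValueError("no alignments to merge")
    merged = merge_intervals(
        [a.interval for a in alignments], merge_distance, stranded
    )
    return ClusterSet(merged, stage="preliminary")


def count_reads_per_cluster(
    alignments: Sequence[AlignmentRecord],
    clusters: ClusterSet,
    count_mode: str = "full",
) -> tuple[dict[str, float], float]:
    """Tally read counts per cluster; returns (per-cluster counts, unassigned).

    Any-overlap assignment: each placement contributes its read count to every
    cluster it overlaps. Multi-placement reads contribute at every site
    (``count_mode="full"``); ``"fractional"`` divides each read's count evenly
    across its placements.
    """
    if count_mode not in ("full", "fractional"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    trees: dict[str, IntervalTree] = {}
    for c in clusters:
        trees.setdefault(c.scaffold, IntervalTree()).addi(c.start, c.end, c.id)

    counts: dict[str, float] = {cid: 0.0 for cid in clusters.ids}
    unassigned = 0.0

    if count_mode == "fractional":
        placements_per_read: dict[int, int] = {}
        for aln in alignments:
            placements_per_read[id(aln.read)] = (
                placements_per_read.get(id(aln.read), 0) + 1
            )

    for aln in alignments:
        weight = float(aln.read.count)
        if count_mode == "fractional":
            weight /= placements_per_read[id(aln.read)]
        tree = trees.get(aln.interval.scaffold)
        overlapping = (
            tree.overlap(aln.interval.start, aln.interval.end) if tree else ()
        )
        if not overlapping:
            unassigned += weight
            continue
        for hit in overlapping:
            counts[hit.data] += weight
    return counts, unassigned


def filter_reference(
    preliminary: ClusterSet,
    ox_counts: Mapping[str, float],
    testis_counts: Mapping[str, float],
    params: ReferenceFilterParams | None = None,
) -> ClusterSet:
    """Apply the count-floor and oxidation-ratio filters to the preliminary set.

    Retained iff NOT(ox < min_count AND testis < min_count) AND
    NOT(ox/testis < min_ox_ratio). testis = 0 with ox > 0 gives ratio +inf
    (passes); ox = 0 with testis > 0 gives ratio 0 (fails the ratio filter).
    """
    if params is None:
        params = ReferenceFilterParams()
    missing = [
        cid
        for cid in preliminary.ids
        if cid not in ox_counts or cid not in testis_counts
    ]
    if missing:
        raise ValueError(
            f"counts missing for {len(missing)} clusters (e.g. {missing[0]})"
        )

    kept = []
    for c in preliminary:
        ox, te = ox_counts[c.id], testis_counts[c.id]
        if ox < params.min_count and te < params.min_count:
            continue
        ratio = float("inf") if te == 0 else ox / te
        if ratio < params.min_ox_ratio:
            continue
        kept.append(c)
    return ClusterSet(kept, stage="final")


def nearest_gene(
    clusters: ClusterSet,
    genes: Sequence[GenomicInterval],
    gene_ids: Sequence[str] | None = None,
    proximity: int = 10_000,
) -> dict[str, tuple[str | None, int | None, bool]]:
    """Closest gene per cluster: (gene id, signed distance, within-proximity flag).

    Distance is 0 for overlap, positive when the gene lies downstream of the
    cluster end, negative when upstream of the cluster start. Ties break to
    the lower-coordinate gene. Clusters on scaffolds without genes map to
    (None, None, False).
    """
    if gene_ids is None:
        gene_ids = [g.id for g in genes]
    by_scaffold: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for g, gid in zip(genes, gene_ids):
        by_scaffold.setdefault(g.scaffold, []).append((g, gid))
    for lst in by_scaffold.values():
        lst.sort(key=lambda t: (t[0].start, t[0].end))

    out: dict[str, tuple[str | None, int | None, bool]] = {}
    for c in clusters:
        candidates = by_scaffold.get(c.scaffold)
        if not candidates:
            out[c.id] = (None, None, False)
            continue
        best: tuple[int, int, str] | None = None  # (abs dist, start, id) for ties
        for g, gid in candidates:
            if g.start < c.end and c.start < g.end:
                dist = 0
            elif g.start >= c.end:
                dist = g.start - c.end
            else:
                dist = -(c.start - g.end)
            key = (abs(dist), g.start)
            if best is None or key < (best[0], best[1]):
                best = (abs(dist), g.start, gid, dist)
        out[c.id] = (best[2], best[3], abs(best[3]) <= proximity)
    return out
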
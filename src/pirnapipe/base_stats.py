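"""Positional base composition and primary/secondary pathway ratio statistics.

Primary-pathway piRNAs start with uridine (1U) but lack adenine at position
10; secondary ("ping-pong") piRNAs start with any base but uridine and carry
adenine at position 10 (10A). The primary/secondary ratio counts reads in
each disjoint category; reads satisfying both or neither are excluded. A 10G
variant is provided for samples with a guanine bias at position 10.

All computation is in the DNA alphabet; display uses RNA letters (U for T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .core_io import CollapsedRead

DNA_BASES = ("A", "C", "G", "T")
RNA_DISPLAY = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass
class PositionalComposition:
    """Per-position base counts and proportions (RNA letters as keys)."""

    counts: dict[int, dict[str, float]]  # position (1-based) -> base -> count
    weighting: str

    def proportions(self, position: int) -> dict[str, float]:
        c = self.counts[position]
        total = sum(c.values())
        if total == 0:
            raise ValueError(f"no observations at position {position}")
        return {b: v / total for b, v in c.items()}


@dataclass
class PathwayRatio:
    n_primary: int
    n_secondary: int
    variant: str

    @property
    def ratio(self) -> float:
        if self.n_secondary == 0:
            return float("inf")
        return self.n_primary / self.n_secondary

    @property
    def undefined_denominator(self) -> bool:
        return self.n_secondary == 0


def base_composition(
    reads: Sequence[CollapsedRead],
    positions: Sequence[int] = (1, 10),
    weighting: str = "by_read_count",
) -> PositionalComposition:
    """Base composition at the given 1-based positions.

    ``by_read_count`` weights each unique sequence by its abundance (the
    default, matching composition over sequenced reads); ``by_unique_sequence``
    weights every unique sequence once. Reads shorter than a position, and N
    bases, are excluded from that position's denominator.
    """
    if not reads:
        raise ValueError("no reads")
    if weighting not in ("by_read_count", "by_unique_sequence"):
        raise ValueError(f"unknown weighting {weighting!r}")

    counts = {
        p: {RNA_DISPLAY[b]: 0.0 for b in DNA_BASES} for p in positions
    }
    for r in reads:
        w = r.count if weighting == "by_read_count" else 1
        for p in positions:
            if len(r.sequence) < p:
                continue
            base = r.sequence[p - 1]
            if base in RNA_DISPLAY:
                counts[p][RNA_DISPLAY[base]] += w
    return PositionalComposition(counts=counts, weighting=weighting)


def pathway_ratio(
    reads: Sequence[CollapsedRead],
    variant: str = "10A",
    weighting: str = "by_read_count",
) -> PathwayRatio:
    """Primary/secondary pathway ratio (1U-not-10X over not-1U-10X).

    ``variant`` selects the position-10 base X (A for the canonical ping-pong
    signature, G for guanine-biased samples). Reads shorter than 10 nt are
    excluded.
    """
    if variant not in ("10A", "10G"):
        raise ValueError(f"unknown variant {variant!r}")
    x = variant[-1]
    n_primary = n_secondary = 0
    for r in reads:
        if len(r.sequence) < 10:
            continue
        w = r.count if weighting == "by_read_count" else 1
        first_u = r.sequence[0] == "T"
        tenth_x = r.sequence[9] == x
        if first_u and not tenth_x:
            n_primary += w
        elif not first_u and tenth_x:
            n_secondary += w
    return PathwayRatio(n_primary=n_primary, n_secondary=n_secondary, variant=variant)


def bias_test(
    composition: PositionalComposition,
    position: int,
    expected: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of base counts at a position, df = 3.

    Defaults to a uniform 1/4 background; a custom background (e.g. genome
    composition) may be supplied as RNA-letter proportions.
    """
    import warnings

    obs = composition.counts[position]
    bases = ["A", "C", "G", "U"]
    observed = [obs[b] for b in bases]
    total = sum(observed)
    if total == 0:
        raise ValueError(f"no observations at position {position}")
    if total < 20:
        warnings.warn(
            f"only {total} observations at position {position}: "
            "chi-square asymptotics unreliable"
        )
    if expected is None:
        expected_counts = [total / 4.0] * 4
    else:
        expected_counts = [total * expected[b] for b in bases]
    stat, p = stats.chisquare(observed, f_exp=expected_counts)
    return float(stat), float(p)
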
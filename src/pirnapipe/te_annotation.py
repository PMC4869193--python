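"""Matching cluster sequences against a classed TE library and testing
per-class enrichment of cluster-hit TEs against the whole library.

The enrichment unit is the distinct TE: a TE hit by several clusters counts
once. Per class, the fraction among hit TEs is compared with the fraction in
the full library by a two-sample test for equality of proportions
(chi-square with continuity correction), flagged at p < 0.1 / 0.05 / 0.01.

Two matching engines exist: ``external`` consumes precomputed 12-column
tabular alignment output (BLAST outfmt 6) and applies the identity
threshold; ``internal`` is a deliberately simple seeded ungapped matcher
(exact 15-mer seed, bidirectional extension, stop when the accumulated
mismatch fraction exceeds 1 - min_identity) adequate for synthetic-scale
work — it is not a BLAST replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .core_io import reverse_complement

TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "RC", "unknown")

_SEED_LEN = 15


@dataclass(frozen=True)
class TEEntry:
    te_id: str
    te_class: str
    sequence: str


@dataclass
class TELibrary:
    entries: list[TEEntry]

    def __post_init__(self):
        ids = [e.te_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("TE ids must be unique")

    def class_of(self, te_id: str) -> str:
        for e in self.entries:
            if e.te_id == te_id:
                return e.te_class
        raise KeyError(te_id)

    def class_proportions(self) -> dict[str, float]:
        n = len(self.entries)
        props: dict[str, float] = {}
        for e in self.entries:
            props[e.te_class] = props.get(e.te_class, 0) + 1
        return {k: v / n for k, v in props.items()}

    def __len__(self):
        return len(self.entries)


def read_te_library(path: str | Path) -> TELibrary:
    """Read a TE library FASTA with the ``>te_id#class`` header dialect."""
    from Bio import SeqIO

    from .core_io import normalize_sequence

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "#" in rec.id:
            te_id, te_class = rec.id.split("#", 1)
            te_class = te_class.split("/")[0]
        else:
            te_id, te_class = rec.id, "unknown"
        entries.append(TEEntry(te_id, te_class, normalize_sequence(str(rec.seq))))
    return TELibrary(entries)


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Parse 12-column BLAST tabular output (query, subject, identity %, ...)."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=cols)
    for c in ("pident", "evalue", "bitscore"):
        df[c] = df[c].astype(float)
    for c in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[c] = df[c].astype(int)
    return df


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _extend_ungapped(
    cluster: str, te: str, ci: int, ti: int, k: int, max_mm_frac: float
) -> tuple[int, int]:
    """Extend a seeded match both ways; return (alignment length, mismatches)."""
    mism = 0
    left = 0
    while ci - left - 1 >= 0 and ti - left - 1 >= 0:
        if cluster[ci - left - 1] != te[ti - left - 1]:
            new_mm = mism + 1
            if new_mm / (k + left + 1) > max_mm_frac:
                break
            mism = new_mm
        left += 1
    right = 0
    while ci + k + right < len(cluster) and ti + k + right < len(te):
        if cluster[ci + k + right] != te[ti + k + right]:
            new_mm = mism + 1
            if new_mm / (k + left + right + 1) > max_mm_frac:
                break
            mism = new_mm
        right += 1
    return k + left + right, mism


def match_clusters_to_tes(
    cluster_seqs: Mapping[str, str],
    library: TELibrary,
    min_identity: float = 0.90,
    engine: str = "internal",
    hits_path: str | Path | None = None,
    min_length: int = 50,
) -> pd.DataFrame:
    """Match cluster sequences to the TE library; rows below min_identity drop.

    Returns a TEHitTable DataFrame with columns cluster_id, te_id, te_class,
    identity, length, score. ``engine="external"`` reads precomputed tabular
    hits from ``hits_path`` instead of aligning.
    """
    if engine == "external":
        if hits_path is None:
            raise ValueError("external engine requires hits_path")
        tab = read_blast_tabular(hits_path)
        classes = {e.te_id: e.te_class for e in library.entries}
        tab = tab[tab["pident"] >= min_identity * 100].copy()
        return pd.DataFrame(
            {
                "cluster_id": tab["qseqid"].to_numpy(),
                "te_id": tab["sseqid"].to_numpy(),
                "te_class": [classes.get(s, "unknown") for s in tab["sseqid"]],
                "identity": tab["pident"].to_numpy() / 100.0,
                "length": tab["length"].to_numpy(),
                "score": tab["bitscore"].to_numpy(),
            }
        )
    if engine != "internal":
        raise ValueError(f"unknown engine {engine!r}")

    max_mm_frac = 1.0 - min_identity
    rows = []
    for cid, cseq in cluster_seqs.items():
        seed_index = _seed_positions(cseq, _SEED_LEN)
        for entry in library.entries:
            best: tuple[int, float] | None = None  # (length, identity)
            for tseq in (entry.sequence, reverse_complement(entry.sequence)):
                for ti in range(0, max(1, len(tseq) - _SEED_LEN + 1), _SEED_LEN):
                    seed = tseq[ti : ti + _SEED_LEN]
                    for ci in seed_index.get(seed, ()):
                        length, mism = _extend_ungapped(
                            cseq, tseq, ci, ti, _SEED_LEN, max_mm_frac
                        )
                        identity = 1.0 - mism / length
                        if length >= min_length and identity >= min_identity:
                            if best is None or length > best[0]:
                                best = (length, identity)
            if best is not None:
                rows.append(
                    {
                        "cluster_id": cid,
                        "te_id": entry.te_id,
                        "te_class": entry.te_class,
                        "identity": best[1],
                        "length": best[0],
                        "score": float(best[0]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "te_id", "te_class", "identity", "length", "score"],
    )


def te_class_enrichment(hits: pd.DataFrame, library: TELibrary) -> pd.DataFrame:
    """Per-class two-proportion test: hit-TE class fraction vs library fraction.

    Returns a table with proportion_hit, proportion_library, p_value and the
    significance flag ('*' p<0.1, '**' p<0.05, '***' p<0.01). Classes present
    among hits but absent from the library are skipped with a warning.
    """
    if hits.empty:
        raise ValueError("no TE hits to test")
    hit_tes = hits.drop_duplicates("te_id")
    n_hit = len(hit_tes)
    n_lib = len(library)
    lib_class_counts: dict[str, int] = {}
    for e in library.entries:
        lib_class_counts[e.te_class] = lib_class_counts.get(e.te_class, 0) + 1

    rows = []
    for te_class in sorted(set(hit_tes["te_class"]) | set(lib_class_counts)):
        k_lib = lib_class_counts.get(te_class, 0)
        if k_lib == 0:
            warnings.warn(f"TE class {te_class!r} absent from library: skipped")
            continue
        k_hit = int((hit_tes["te_class"] == te_class).sum())
        stat, p = two_proportion_test(k_hit, n_hit, k_lib, n_lib)
        flag = "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""
        rows.append(
            {
                "te_class": te_class,
                "n_hit": k_hit,
                "proportion_hit": k_hit / n_hit,
                "n_library": k_lib,
                "proportion_library": k_lib / n_lib,
                "chi2": stat,
                "p_value": p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> tuple[float, float]:
    """Two-sample equality-of-proportions chi-square with continuity correction.

    Identical to the Yates-corrected chi-square on the 2x2 table (R prop.test).
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if k1 == k2 == 0 or (k1 == n1 and k2 == n2):
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def fraction_clusters_with_hit(hits: pd.DataFrame, cluster_ids: Sequence[str]) -> float:
    """Fraction of clusters with at least one TE hit."""
    if not len(cluster_ids):
        raise ValueError("no clusters")
    hit_clusters = set(hits["cluster_id"]) if not hits.empty else set()
    return len(hit_clusters & set(cluster_ids)) / len(cluster_ids)


def mirna_contamination_flag(
    cluster_seqs: Mapping[str, str], mirna_seqs: Mapping[str, str]
) -> bool:
    """QC flag: True when no cluster sequence contains a known miRNA hairpin.

    Mirrors the reference QC that no cluster region overlaps a known miRNA.
    """
    for cseq in cluster_seqs.values():
        for mseq in mirna_seqs.values():
            if mseq in cseq or reverse_complement(mseq) in cseq:
                return False
    return True
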
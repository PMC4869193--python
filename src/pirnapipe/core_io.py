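"""Domain types and readers/writers for the formats the pipeline touches.

Coordinates are 0-based half-open everywhere (BED convention). All sequence
comparison happens in the DNA alphabet: U is converted to T on input, and
display-side composition reports convert back to RNA letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

VALID_ROLES = frozenset(
    {"oxidized_testis", "testis", "ovary", "somatic_control", "tumor"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Upper-case and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, strand in {+, -, .}."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.scaffold:
            raise ValueError("scaffold name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.scaffold}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence with its summed read count."""

    sequence: str
    count: int
    sample_id: str = ""

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")


@dataclass(frozen=True)
class AlignmentRecord:
    """One exact genomic placement of a collapsed read."""

    read: CollapsedRead
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError("alignment strand must be + or -")
        if self.interval.length != len(self.read.sequence):
            raise ValueError("alignment span must equal read length")


@dataclass
class ClusterSet:
    """Ordered, non-overlapping genomic intervals forming a cluster reference.

    ``ids`` are stable ``scaffold:start-end`` strings. ``stage`` distinguishes
    the preliminary (merge-only) reference from the final (filtered) one.
    """

    clusters: list[GenomicInterval]
    stage: str = "preliminary"

    def __post_init__(self):
        if self.stage not in ("preliminary", "final"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.clusters = sorted(
            self.clusters, key=lambda c: (c.scaffold, c.start, c.end)
        )
        prev: GenomicInterval | None = None
        for c in self.clusters:
            if prev is not None and prev.scaffold == c.scaffold and c.start < prev.end:
                raise ValueError(
                    f"overlapping clusters {prev.id} and {c.id}; merge first"
                )
            prev = c

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


@dataclass
class CountMatrix:
    """Clusters x samples read-count table with sample role labels."""

    cluster_ids: list[str]
    sample_ids: list[str]
    counts: "pd.DataFrame"
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        import pandas as pd

        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(
                self.counts, index=self.cluster_ids, columns=self.sample_ids
            )
        if list(self.counts.index) != list(self.cluster_ids) or list(
            self.counts.columns
        ) != list(self.sample_ids):
            raise ValueError("counts table inconsistent with cluster/sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for s, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for sample {s}")

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.sample_ids if self.roles.get(s) == role]

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="cluster_id")


@dataclass(frozen=True)
class SampleSheetRow:
    sample_id: str
    role: str
    group: str

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class SampleSheet:
    rows: list[SampleSheetRow]

    def __post_init__(self):
        ids = [r.sample_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")

    def with_role(self, role: str) -> list[SampleSheetRow]:
        return [r for r in self.rows if r.role == role]

    def require_reference_pair(self) -> tuple[str, str]:
        """Return (oxidized_testis, testis) sample ids; exactly one of each."""
        ox = self.with_role("oxidized_testis")
        te = self.with_role("testis")
        if len(ox) != 1 or len(te) != 1:
            raise ValueError(
                "reference construction requires exactly one oxidized_testis "
                f"and one testis sample (got {len(ox)} and {len(te)})"
            )
        return ox[0].sample_id, te[0].sample_id

    @property
    def roles(self) -> dict[str, str]:
        return {r.sample_id: r.role for r in self.rows}


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet with columns sample_id, role, group."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("sample_id", "sample"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            rows.append(SampleSheetRow(parts[0], parts[1], parts[2]))
    return SampleSheet(rows)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\tgroup\n")
        for r in sheet.rows:
            fh.write(f"{r.sample_id}\t{r.role}\t{r.group}\n")


def read_fasta_genome(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as a scaffold -> sequence mapping.

    Scaffold names are the header token before the first whitespace.
    Sequences are upper-cased and U is stored as T.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id  # SeqIO already splits at whitespace
        if name in genome:
            raise ValueError(f"duplicate scaffold name {name!r} in {path}")
        genome[name] = normalize_sequence(str(rec.seq))
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def _collapsed_count_from_header(header: str) -> int | None:
    """Parse the 'name-<count>' collapsed-FASTA dialect; None if absent."""
    token = header.split()[0]
    if "-" in token:
        tail = token.rsplit("-", 1)[1]
        if tail.isdigit():
            return int(tail)
    return None


def read_small_rna(
    path: str | Path,
    format: str | None = None,
    sample_id: str = "",
    collapsed: bool = False,
) -> list[CollapsedRead]:
    """Read small-RNA reads (FASTQ or FASTA) and collapse identical sequences.

    ``collapsed=True`` enables the pre-collapsed FASTA dialect in which the
    header token ends in ``-<count>``. Collapsing is case-insensitive and
    U/T-insensitive; counts of identical sequences are summed.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in (".fq", ".fastq") else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")

    tallies: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                raise ValueError(f"empty sequence record {rec.id!r} in {path}")
            n = 1
            if collapsed and format == "fasta":
                parsed = _collapsed_count_from_header(rec.id)
                if parsed is not None:
                    n = parsed
            tallies[seq] = tallies.get(seq, 0) + n
    except ValueError as exc:
        raise ValueError(f"malformed {format} record in {path}: {exc}") from exc
    return [
        CollapsedRead(seq, count, sample_id) for seq, count in sorted(tallies.items())
    ]


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads in the 'name-<count>' FASTA dialect."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">seq{i}-{r.count}\n{r.sequence}\n")


def write_bed(clusters: ClusterSet, path: str | Path) -> None:
    """Write a ClusterSet as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.scaffold}\t{c.start}\t{c.end}\t{c.id}\t.\t{c.strand}\n")


def read_bed(
    path: str | Path, stage: str = "preliminary", one_based: bool = False
) -> ClusterSet:
    """Read a BED file into a ClusterSet.

    ``one_based=True`` accepts the 1-based inclusive dialect (coordinates are
    shifted by -1 on the start).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            scaffold = parts[0]
            start, end = int(parts[1]), int(parts[2])
            if one_based:
                start -= 1
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            intervals.append(GenomicInterval(scaffold, start, end, strand))
    return ClusterSet(intervals, stage=stage)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file as a plain interval list (genes, masks); may overlap."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return intervals


@dataclass(frozen=True)
class RepeatInterval:
    """One RepeatMasker annotation: a masked interval plus its repeat class."""

    interval: GenomicInterval
    repeat_class: str
    repeat_name: str = ""


def read_repeatmasker_out(path: str | Path) -> list[RepeatInterval]:
    """Parse a RepeatMasker .out file into classed repeat intervals.

    RepeatMasker .out coordinates are 1-based inclusive; converted to 0-based
    half-open. The class column may carry a family suffix (``LTR/Gypsy``);
    the part before the slash is the class.
    """
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or not parts[0].replace(".", "").isdigit():
                continue  # header / blank lines
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
            scaffold = parts[4]
            start = int(parts[5]) - 1
            end = int(parts[6])
            name = parts[9]
            rclass = parts[10].split("/")[0]
            repeats.append(
                RepeatInterval(GenomicInterval(scaffold, start, end), rclass, name)
            )
    return repeats


def read_repeat_mask_bed(path: str | Path) -> list[RepeatInterval]:
    """Read a BED mask whose name column (4th field) carries the repeat class."""
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            rclass = parts[3] if len(parts) >= 4 else "Unknown"
            repeats.append(
                RepeatInterval(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2])), rclass
                )
            )
    return repeats


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read any FASTA (miRNA hairpins, tRNAs, TE library) as id -> DNA sequence."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            warnings.warn(f"duplicate FASTA id {rec.id!r}; keeping the first")
            continue
        seqs[rec.id] = normalize_sequence(str(rec.seq))
    return seqs


def extract_cluster_sequences(
    clusters: ClusterSet, genome: Mapping[str, str]
) -> dict[str, str]:
    """Pull cluster sequences from the genome by coordinates (forward strand)."""
    out = {}
    for c in clusters:
        if c.scaffold not in genome:
            raise KeyError(f"scaffold {c.scaffold!r} absent from genome")
        out[c.id] = genome[c.scaffold][c.start : c.end]
    return out
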
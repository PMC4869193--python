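"""Synthetic genomes, planted piRNA clusters, contaminants, and per-sample
small-RNA read sets with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
read lengths peak at 28 nt (range 25-32); germline reads carry the 1U/10A
bias (77 % uridine at position 1, 49.1 % adenine at position 10); somatic
reads drawn from separate cluster-resident species carry a guanine bias at
position 1; miRNA-hairpin, tRNA and random-degradation contaminants are
mixed in at configured fractions; and the oxidized-testis role depletes all
non-piRNA reads to a small survival fraction, mimicking periodate oxidation
of RNAs lacking 3' 2'-O-methylation. Planted clusters are spaced further
apart than the merge distance so the ground truth is unambiguous.

All randomness flows from a single seed through named child generators, so
each sample is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    CollapsedRead,
    GenomicInterval,
    RepeatInterval,
    SampleSheet,
    SampleSheetRow,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# contaminant species abundances: mild skew, so that no single fragment can
# mimic an oxidation-resistant locus and break the unambiguous planted truth
CONTAMINANT_SIGMA = 0.5

# read-length law: 25..32 nt with the mode at 28
LENGTHS = np.arange(25, 33)
LENGTH_PROBS = np.array([0.03, 0.08, 0.16, 0.30, 0.18, 0.12, 0.08, 0.05])


@dataclass
class SimulationConfig:
    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 50_000
    n_clusters: int = 20
    cluster_length_range: tuple[int, int] = (1_200, 2_400)
    cluster_spacing: int = 5_000  # > merge_distance, keeps truth unambiguous
    n_species_per_cluster: int = 60
    n_somatic_species_per_cluster: int = 40
    testis_only_fraction: float = 0.4
    te_cluster_fraction: float = 0.4  # fraction of clusters bearing a TE copy
    n_tes: int = 10
    te_length: int = 300
    te_copy_divergence: float = 0.06  # per-base mutation rate of planted copies
    n_mirnas: int = 20
    mirna_length: int = 80
    n_trnas: int = 15
    trna_length: int = 75
    n_simple_repeats: int = 10
    depth: int = 100_000
    germline_bias: tuple[float, float] = (0.77, 0.491)  # P(1U), P(10A)
    somatic_bias: tuple[float, float] = (0.50, 0.40)  # P(1G), P(10G)
    mirna_fraction: float = 0.05
    trna_fraction: float = 0.03
    degradation_fraction: float = 0.07
    n_degradation_species: int = 500
    oxidation_survival: float = 0.02
    n_misc_loci: int = 0  # abundant unmethylated loci; exercise the ratio filter
    misc_fraction: float = 0.04
    tumor_fold: float = 4.5
    # few shared clusters planted up in tumor samples: median-of-ratios
    # normalization assumes most features unchanged, and the emulated studies
    # see only a few percent of clusters differentially expressed
    n_tumor_up: int = 3
    # lognormal sd of per-sample cluster expression. Kept small: with a
    # planted fold only 12.5 % above the 4-fold detection threshold and two
    # samples per group, planted changes are identifiable only when replicate
    # variability is near-technical; real biological replicates vary more
    # (see the methods note).
    biological_cv: float = 0.03
    species_abundance_sigma: float = 1.0

    def __post_init__(self):
        for p in (
            *self.germline_bias,
            *self.somatic_bias,
            self.mirna_fraction,
            self.trna_fraction,
            self.degradation_fraction,
            self.oxidation_survival,
            self.testis_only_fraction,
            self.te_cluster_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.cluster_spacing <= 1000:
            raise ValueError("cluster_spacing must exceed the merge distance")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass(frozen=True)
class Species:
    """One piRNA species: a fixed genomic locus emitting identical reads."""

    sequence: str
    cluster_index: int
    compartment: str  # germline | somatic
    weight: float  # within-cluster relative abundance


@dataclass
class PlantedCluster:
    cluster_index: int
    interval: GenomicInterval  # span of planted species (expected recovery)
    region: GenomicInterval  # full planted region
    label: str  # testis_only | shared
    te_id: str | None
    tumor_fold: float


@dataclass
class GroundTruth:
    clusters: list[PlantedCluster]
    species: list[Species]
    te_library: dict[str, tuple[str, str]]  # te_id -> (class, sequence)
    mirnas: dict[str, str]
    trnas: dict[str, str]
    repeat_mask: list[RepeatInterval]
    misc_loci: list[GenomicInterval]
    misc_sequences: list[str]
    germline_1u_realized: float = 0.0  # abundance-weighted realized P(1U)
    expected_counts: dict[str, dict[int, float]] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)


TE_CLASS_CYCLE = ("DNA", "LINE", "SINE", "LTR", "unknown")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[rng.integers(3)]
    return "".join(chars)


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named child generator: stable across processes (no str hash salting)."""
    tag = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence(config.seed, spawn_key=(tag,))
    return np.random.default_rng(ss)


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], GroundTruth]:
    """Build the synthetic genome and the ground-truth skeleton.

    Scaffolds are random sequence with planted cluster loci (a fraction of
    which embed a diverged TE copy), miRNA hairpins, tRNAs and simple-repeat
    runs in the inter-cluster gaps. piRNA species loci within clusters are
    edited so read start/position-10 bases realize the configured biases.
    Deterministic given the seed.
    """
    rng = _rng_for(config, "genome")

    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    seqs: dict[str, list[str]] = {
        s: list(_random_seq(rng, config.scaffold_length)) for s in scaffolds
    }

    te_library: dict[str, tuple[str, str]] = {}
    for i in range(config.n_tes):
        te_class = TE_CLASS_CYCLE[i % len(TE_CLASS_CYCLE)]
        te_library[f"TE_{i + 1}"] = (te_class, _random_seq(rng, config.te_length))
    mirnas = {
        f"mir-{i + 1}": _random_seq(rng, config.mirna_length)
        for i in range(config.n_mirnas)
    }
    trnas = {
        f"trna-{i + 1}": _random_seq(rng, config.trna_length)
        for i in range(config.n_trnas)
    }

    # --- lay out clusters scaffold by scaffold -------------------------------
    margin = 2_000
    placements: list[tuple[str, int, int]] = []
    si, cursor = 0, margin
    for _ in range(config.n_clusters + config.n_misc_loci):
        length = int(rng.integers(*config.cluster_length_range))
        while cursor + length + margin > config.scaffold_length:
            si += 1
            cursor = margin
            if si >= config.n_scaffolds:
                raise ValueError("clusters do not fit on the configured scaffolds")
        placements.append((scaffolds[si], cursor, cursor + length))
        cursor += length + config.cluster_spacing

    misc_placements = placements[config.n_clusters :]
    placements = placements[: config.n_clusters]

    n_testis_only = int(round(config.testis_only_fraction * config.n_clusters))
    n_te_bearing = int(round(config.te_cluster_fraction * config.n_clusters))
    order = rng.permutation(config.n_clusters)
    testis_only_set = set(order[:n_testis_only].tolist())
    te_bearing = set(rng.permutation(config.n_clusters)[:n_te_bearing].tolist())
    shared = [i for i in range(config.n_clusters) if i not in testis_only_set]
    tumor_up = set(
        rng.choice(shared, size=min(config.n_tumor_up, len(shared)), replace=False).tolist()
    )

    clusters: list[PlantedCluster] = []
    species: list[Species] = []
    te_ids = list(te_library)
    for ci, (scaffold, start, end) in enumerate(placements):
        te_id = None
        te_zone: tuple[int, int] | None = None
        if ci in te_bearing:
            te_id = te_ids[ci % len(te_ids)]
            te_seq = _mutate(
                rng, te_library[te_id][1], config.te_copy_divergence
            )
            mid = (start + end) // 2 - len(te_seq) // 2
            seqs[scaffold][mid : mid + len(te_seq)] = list(te_seq)
            te_zone = (mid, mid + len(te_seq))

        label = "testis_only" if ci in testis_only_set else "shared"
        fold = config.tumor_fold if ci in tumor_up else 1.0

        n_som = 0 if label == "testis_only" else config.n_somatic_species_per_cluster
        loci = _place_species_loci(
            rng, start, end, te_zone, config.n_species_per_cluster + n_som
        )
        # loci come back position-ordered; interleave the two compartments
        germline_idx = set(
            rng.permutation(len(loci))[: config.n_species_per_cluster].tolist()
        )
        weights_g = rng.lognormal(0.0, config.species_abundance_sigma,
                                  config.n_species_per_cluster)
        weights_s = rng.lognormal(0.0, config.species_abundance_sigma, n_som)
        # anchor the cluster ends with clearly detectable species so the
        # planted span stays recoverable after low-abundance filtering
        g_positions = [j for j in range(len(loci)) if j in germline_idx]
        g_order = sorted(range(len(g_positions)), key=lambda i: loci[g_positions[i]][0])
        for anchor in (g_order[0], g_order[-1]):
            weights_g[anchor] = max(weights_g[anchor], 1.0)

        # shift loci whose bias positions collide with an already edited base:
        # overlapping species otherwise overwrite each other's planted start /
        # position-10 bases and dilute the configured bias
        claimed: set[int] = set()
        adjusted: list[tuple[int, int, str]] = []
        for pos, length, strand in loci:
            for delta in (0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5):
                p = pos + delta
                if p < start or p + length > end:
                    continue
                cells = _edit_positions(p, length, strand)
                if claimed.isdisjoint(cells):
                    claimed.update(cells)
                    pos = p
                    break
            adjusted.append((pos, length, strand))
        loci = adjusted

        span_lo, span_hi = config.scaffold_length, 0
        for j, (pos, length, strand) in enumerate(loci):
            germline = j in germline_idx
            p1, p10 = config.germline_bias if germline else config.somatic_bias
            base1 = ("T" if germline else "G") if rng.random() < p1 else \
                rng.choice([b for b in "ACG"] if germline else ["A", "C", "T"])
            base10 = ("A" if germline else "G") if rng.random() < p10 else \
                rng.choice([b for b in "CGT"] if germline else ["A", "C", "T"])
            _edit_for_read_bases(seqs[scaffold], pos, length, strand, base1, base10)
            if germline:  # the oxidized sample can only recover germline loci
                span_lo, span_hi = min(span_lo, pos), max(span_hi, pos + length)
        gi = si_ = 0
        for j, (pos, length, strand) in enumerate(loci):
            segment = "".join(seqs[scaffold][pos : pos + length])
            read_seq = segment if strand == "+" else reverse_complement(segment)
            germline = j in germline_idx
            if germline:
                w, gi = weights_g[gi], gi + 1
            else:
                w, si_ = weights_s[si_], si_ + 1
            species.append(
                Species(read_seq, ci, "germline" if germline else "somatic", float(w))
            )

        clusters.append(
            PlantedCluster(
                ci,
                GenomicInterval(scaffold, span_lo, span_hi),
                GenomicInterval(scaffold, start, end),
                label,
                te_id,
                fold,
            )
        )

    # --- misc unmethylated loci (ratio-filter fodder) ------------------------
    misc_loci, misc_sequences = [], []
    for scaffold, start, end in misc_placements:
        length = 28
        pos = (start + end) // 2
        misc_loci.append(GenomicInterval(scaffold, pos, pos + length))
        misc_sequences.append("".join(seqs[scaffold][pos : pos + length]))

    # --- plant contaminant features in inter-cluster gaps --------------------
    repeat_mask: list[RepeatInterval] = []
    small_features: list[tuple[str, str, str]] = []  # (kind, name, seq)
    for name, seq in mirnas.items():
        small_features.append(("mirna", name, seq))
    for name, seq in trnas.items():
        small_features.append(("trna", name, seq))
    for i in range(config.n_simple_repeats):
        small_features.append(("Simple_repeat", f"(AT)n_{i + 1}", "AT" * 30))

    # features must stay > merge distance away from planted piRNA loci so
    # their degradation fragments can never bridge into a cluster; among
    # themselves they only need to not overlap
    pirna_zones: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    for c in clusters:
        pirna_zones[c.region.scaffold].append((c.region.start, c.region.end))
    for iv in misc_loci:
        pirna_zones[iv.scaffold].append((iv.start, iv.end))
    feature_zones: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}

    for kind, name, seq in small_features:
        placed = False
        for _ in range(5000):
            scaffold = scaffolds[int(rng.integers(config.n_scaffolds))]
            pos = int(rng.integers(margin, config.scaffold_length - margin - len(seq)))
            if all(
                pos + len(seq) + 1300 <= s or e + 1300 <= pos
                for s, e in pirna_zones[scaffold]
            ) and all(
                pos + len(seq) + 50 <= s or e + 50 <= pos
                for s, e in feature_zones[scaffold]
            ):
                seqs[scaffold][pos : pos + len(seq)] = list(seq)
                feature_zones[scaffold].append((pos, pos + len(seq)))
                if kind in ("trna", "Simple_repeat"):
                    rclass = "tRNA" if kind == "trna" else "Simple_repeat"
                    repeat_mask.append(
                        RepeatInterval(
                            GenomicInterval(scaffold, pos, pos + len(seq)), rclass, name
                        )
                    )
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place feature {name} on the genome")

    genome = {s: "".join(chars) for s, chars in seqs.items()}

    # realized abundance-weighted germline 1U proportion
    g_species = [sp for sp in species if sp.compartment == "germline"]
    wsum = sum(sp.weight for sp in g_species)
    realized = sum(sp.weight for sp in g_species if sp.sequence[0] == "T") / wsum

    truth = GroundTruth(
        clusters=clusters,
        species=species,
        te_library=te_library,
        mirnas=mirnas,
        trnas=trnas,
        repeat_mask=repeat_mask,
        misc_loci=misc_loci,
        misc_sequences=misc_sequences,
        germline_1u_realized=realized,
        labels={c.cluster_index: c.label for c in clusters},
    )
    return genome, truth


def _place_species_loci(
    rng: np.random.Generator,
    start: int,
    end: int,
    te_zone: tuple[int, int] | None,
    n: int,
) -> list[tuple[int, int, str]]:
    """Choose species (pos, length, strand) inside a cluster, avoiding the TE copy.

    Placement is stratified across the allowed span so that coverage stays
    dense even after low-abundance filtering drops a few species: no run of
    dropped species can open a gap anywhere near the merge distance.
    """
    max_len = int(LENGTHS.max())
    allowed: list[tuple[int, int]] = []
    if te_zone:
        if te_zone[0] - start > max_len:
            allowed.append((start, te_zone[0]))
        if end - te_zone[1] > max_len:
            allowed.append((te_zone[1], end))
    else:
        allowed.append((start, end))
    total = sum(e - s for s, e in allowed)

    loci: list[tuple[int, int, str]] = []
    remaining = n
    for i, (s, e) in enumerate(allowed):
        k = remaining if i == len(allowed) - 1 else max(
            1, int(round(n * (e - s) / total))
        )
        k = min(k, remaining)
        stratum = (e - s - max_len) / max(k, 1)
        for j in range(k):
            length = int(rng.choice(LENGTHS, p=LENGTH_PROBS))
            lo = s + int(j * stratum)
            hi = min(s + int((j + 1) * stratum), e - length)
            pos = int(rng.integers(lo, max(hi, lo + 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append((pos, length, strand))
        remaining -= k
    return loci


def _edit_positions(pos: int, length: int, strand: str) -> tuple[int, int]:
    """Genome offsets a species' start / position-10 edits touch."""
    if strand == "+":
        return (pos, pos + 9)
    return (pos + length - 1, pos + length - 10)


def _edit_for_read_bases(
    chars: list[str], pos: int, length: int, strand: str, base1: str, base10: str
) -> None:
    """Edit the genome so the read from (pos, length, strand) starts with base1
    and carries base10 at its 10th position."""
    if strand == "+":
        chars[pos] = base1
        chars[pos + 9] = base10
    else:
        chars[pos + length - 1] = _COMPLEMENT[base1]
        chars[pos + length - 10] = _COMPLEMENT[base10]


# --------------------------------------------------------------------------
# sample simulation
# --------------------------------------------------------------------------

_ROLE_IS_OXIDIZED = {"oxidized_testis"}
_GERMLINE_ROLES = {"oxidized_testis", "testis", "ovary"}


def default_sample_sheet() -> SampleSheet:
    """Six samples: one oxidized testis, one testis, two benign controls
    (hyperpigmented skin), two invasive-melanoma tumors."""
    return SampleSheet(
        [
            SampleSheetRow("ox_testis", "oxidized_testis", "germline"),
            SampleSheetRow("testis", "testis", "germline"),
            SampleSheetRow("HP1", "somatic_control", "HP"),
            SampleSheetRow("HP2", "somatic_control", "HP"),
            SampleSheetRow("IM1", "tumor", "IM"),
            SampleSheetRow("IM2", "tumor", "IM"),
        ]
    )


def _contaminant_species(
    rng: np.random.Generator,
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[tuple[str, str, float]]:
    """(category, sequence, weight) rows for miRNA/tRNA/degradation reads."""
    rows: list[tuple[str, str, float]] = []

    def windows(pool: Sequence[str], n: int, category: str):
        for _ in range(n):
            src = pool[int(rng.integers(len(pool)))]
            length = int(rng.choice(LENGTHS, p=LENGTH_PROBS))
            if len(src) <= length:
                continue
            off = int(rng.integers(0, len(src) - length))
            rows.append(
                (category, src[off : off + length], float(rng.lognormal(0.0, CONTAMINANT_SIGMA)))
            )

    windows(list(truth.mirnas.values()), 80, "mirna")
    windows(list(truth.trnas.values()), 60, "trna")

    # degradation fragments: random genome windows outside planted clusters
    # (degradation of abundant transcripts elsewhere on the genome)
    cluster_regions: dict[str, list[tuple[int, int]]] = {}
    for c in truth.clusters:
        cluster_regions.setdefault(c.region.scaffold, []).append(
            (c.region.start, c.region.end)
        )
    scaffolds = sorted(genome)
    placed = 0
    while placed < config.n_degradation_species:
        scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
        length = int(rng.choice(LENGTHS, p=LENGTH_PROBS))
        pos = int(rng.integers(0, len(genome[scaffold]) - length))
        pad = 1_100  # stay beyond merge distance of planted clusters
        if any(
            pos < e + pad and s - pad < pos + length
            for s, e in cluster_regions.get(scaffold, ())
        ):
            continue
        rows.append(
            (
                "degradation",
                genome[scaffold][pos : pos + length],
                float(rng.lognormal(0.0, CONTAMINANT_SIGMA)),
            )
        )
        placed += 1
    for seq in truth.misc_sequences:
        rows.append(("misc", seq, 1.0))
    return rows


def _cluster_role_multiplier(cluster: PlantedCluster, role: str) -> float:
    if role in _GERMLINE_ROLES:
        return 0.3 if role == "ovary" else 1.0
    if cluster.label == "testis_only":
        return 0.0
    return cluster.tumor_fold if role == "tumor" else 1.0


def simulate_sample(
    genome: Mapping[str, str],
    truth: GroundTruth,
    role: str,
    config: SimulationConfig,
    sample_id: str | None = None,
) -> tuple[list[CollapsedRead], dict[int, float]]:
    """Draw one sample's collapsed reads plus its expected per-cluster counts.

    Reads are multinomial draws over the planted species (germline species
    for germline roles, somatic species for somatic roles) and contaminant
    fragments; oxidized samples keep only ``oxidation_survival`` of the
    non-piRNA mass. Deterministic given the config seed and sample id.
    """
    if role not in {"oxidized_testis", "testis", "ovary", "somatic_control", "tumor"}:
        raise ValueError(f"unknown role {role!r}")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    sample_id = sample_id or role
    rng = _rng_for(config, f"sample:{sample_id}")

    compartment = "germline" if role in _GERMLINE_ROLES else "somatic"
    jitter = {
        c.cluster_index: float(np.exp(rng.normal(0.0, config.biological_cv)))
        for c in truth.clusters
    }
    cluster_mult = {
        c.cluster_index: _cluster_role_multiplier(c, role) * jitter[c.cluster_index]
        for c in truth.clusters
    }

    seqs: list[str] = []
    weights: list[float] = []
    cluster_of: list[int] = []  # -1 for contaminants
    for sp in truth.species:
        if sp.compartment != compartment:
            continue
        m = cluster_mult[sp.cluster_index]
        if m <= 0:
            continue
        seqs.append(sp.sequence)
        weights.append(sp.weight * m)
        cluster_of.append(sp.cluster_index)

    pirna_mass = (
        1.0
        - config.mirna_fraction
        - config.trna_fraction
        - config.degradation_fraction
        - (config.misc_fraction if truth.misc_sequences else 0.0)
    )
    w = np.asarray(weights, dtype=float)
    w = w / w.sum() * pirna_mass

    cont = _contaminant_species(rng, genome, truth, config)
    cat_mass = {
        "mirna": config.mirna_fraction,
        "trna": config.trna_fraction,
        "degradation": config.degradation_fraction,
        "misc": config.misc_fraction if truth.misc_sequences else 0.0,
    }
    survival = config.oxidation_survival if role in _ROLE_IS_OXIDIZED else 1.0
    cw: list[float] = []
    for category, seq, weight in cont:
        seqs.append(seq)
        cluster_of.append(-1)
        cw.append(weight)
    cw_arr = np.asarray(cw, dtype=float)
    # normalize contaminant weights within each category to its mass x survival
    cats = [c for c, _, _ in cont]
    cw_final = np.zeros_like(cw_arr)
    for category in ("mirna", "trna", "degradation", "misc"):
        idx = [i for i, c in enumerate(cats) if c == category]
        if not idx:
            continue
        sub = cw_arr[idx]
        if sub.sum() > 0:
            cw_final[idx] = sub / sub.sum() * cat_mass[category] * survival
    all_w = np.concatenate([w, cw_final])
    all_w = all_w / all_w.sum()

    counts = rng.multinomial(config.depth, all_w)

    tallies: dict[str, int] = {}
    for seq, n in zip(seqs, counts):
        if n:
            tallies[seq] = tallies.get(seq, 0) + int(n)
    reads = [
        CollapsedRead(s, n, sample_id) for s, n in sorted(tallies.items())
    ]

    expected = {c.cluster_index: 0.0 for c in truth.clusters}
    for i, ci in enumerate(cluster_of[: len(w)]):
        expected[ci] += all_w[i] * config.depth
    truth.expected_counts[sample_id] = expected
    return reads, expected


def simulate_dataset(
    config: SimulationConfig, sheet: SampleSheet | None = None
) -> tuple[dict[str, str], GroundTruth, SampleSheet, dict[str, list[CollapsedRead]]]:
    """Genome + ground truth + one read set per sample-sheet row."""
    if sheet is None:
        sheet = default_sample_sheet()
    genome, truth = simulate_genome(config)
    samples = {
        row.sample_id: simulate_sample(genome, truth, row.role, config, row.sample_id)[0]
        for row in sheet.rows
    }
    return genome, truth, sheet, samples


def write_ground_truth_bed(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        for c in truth.clusters:
            fh.write(
                f"{c.interval.scaffold}\t{c.interval.start}\t{c.interval.end}\t"
                f"cluster_{c.cluster_index}\t.\t.\t{c.label}\n"
            )


def write_fastq(reads: Sequence[CollapsedRead], path) -> None:
    """Expand collapsed reads into a plain FASTQ (constant quality)."""
    with open(path, "w") as fh:
        i = 0
        for r in reads:
            for _ in range(r.count):
                i += 1
                fh.write(f"@read_{i}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
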
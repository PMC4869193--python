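"""End-to-end orchestration on simulated data.

Runs the full flow — simulate, prefilter, map, merge, reference filters,
quantify, classify, base statistics, TE annotation, differential expression —
and returns every intermediate result, optionally writing the standard
artifacts to a directory. Used by the `run` subcommand and by the
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .base_stats import PathwayRatio, PositionalComposition, base_composition, pathway_ratio
from .cluster_reference import (
    ReferenceFilterParams,
    count_reads_per_cluster,
    filter_reference,
    merge_alignments,
)
from .core_io import ClusterSet, CountMatrix, SampleSheet, extract_cluster_sequences
from .diffexp import DEResult, differential_expression, results_to_frame
from .exact_mapper import build_index, map_reads
from .prefilter import prefilter_reads
from .quantify_classify import (
    ClassificationParams,
    classify_clusters,
    expression_accounting,
    quantify,
)
from .synthetic_data import GroundTruth, SimulationConfig, simulate_dataset
from .te_annotation import (
    TELibrary,
    TEEntry,
    fraction_clusters_with_hit,
    match_clusters_to_tes,
    mirna_contamination_flag,
    te_class_enrichment,
)


@dataclass
class PipelineResult:
    config: SimulationConfig
    truth: GroundTruth
    sheet: SampleSheet
    preliminary: ClusterSet
    final: ClusterSet
    matrix: CountMatrix
    labels: dict[str, str]
    label_counts: dict[str, int]
    composition: PositionalComposition
    ratios: dict[str, PathwayRatio]
    te_hits: pd.DataFrame
    te_enrichment: pd.DataFrame
    te_fraction: float
    mirna_clean: bool
    de_results: list[DEResult]
    unassigned: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    seed: int = 0,
    out_dir: str | Path | None = None,
    config: SimulationConfig | None = None,
    params: ReferenceFilterParams | None = None,
) -> PipelineResult:
    if config is None:
        config = SimulationConfig(seed=seed)
    if params is None:
        params = ReferenceFilterParams()

    genome, truth, sheet, samples = simulate_dataset(config)
    ox_id, testis_id = sheet.require_reference_pair()

    index = build_index(genome)

    def prep(sample_id: str, low_abundance: bool):
        return prefilter_reads(
            samples[sample_id],
            mirna_seqs=truth.mirnas,
            trna_seqs=truth.trnas,
            min_count=params.min_count if low_abundance else None,
        )

    ox_reads = prep(ox_id, low_abundance=True)
    ox_alns = map_reads(ox_reads, index, genome)
    if not ox_alns:
        raise RuntimeError("cluster_reference stage: no oxidized-testis alignments")

    preliminary = merge_alignments(
        ox_alns, params.merge_distance, params.stranded_merge
    )
    ox_counts, _ = count_reads_per_cluster(ox_alns, preliminary)
    testis_alns = map_reads(prep(testis_id, False), index, genome)
    testis_counts, _ = count_reads_per_cluster(testis_alns, preliminary)
    final = filter_reference(preliminary, ox_counts, testis_counts, params)

    sample_alns = {ox_id: ox_alns, testis_id: testis_alns}
    for row in sheet.rows:
        if row.sample_id not in sample_alns:
            sample_alns[row.sample_id] = map_reads(
                prep(row.sample_id, False), index, genome
            )
    matrix, unassigned = quantify(sample_alns, final, sheet)

    class_params = ClassificationParams()
    labels = classify_clusters(matrix, class_params)
    summary = expression_accounting(matrix, labels, class_params.expressed_min)

    # base statistics on oxidized reads mapped to the reference
    mapped_ox = _reads_mapped_to_reference(sample_alns[ox_id], final)
    composition = base_composition(mapped_ox, positions=(1, 10))
    ratios = {v: pathway_ratio(mapped_ox, variant=v) for v in ("10A", "10G")}

    library = TELibrary(
        [TEEntry(tid, cls, seq) for tid, (cls, seq) in truth.te_library.items()]
    )
    cluster_seqs = extract_cluster_sequences(final, genome)
    te_hits = match_clusters_to_tes(cluster_seqs, library, min_identity=0.90)
    te_fraction = fraction_clusters_with_hit(te_hits, final.ids)
    te_enrichment = (
        te_class_enrichment(te_hits, library) if not te_hits.empty else pd.DataFrame()
    )
    mirna_clean = mirna_contamination_flag(cluster_seqs, truth.mirnas)

    de_results = differential_expression(matrix, "somatic_control", "tumor")

    result = PipelineResult(
        config=config,
        truth=truth,
        sheet=sheet,
        preliminary=preliminary,
        final=final,
        matrix=matrix,
        labels=labels,
        label_counts=summary.label_counts,
        composition=composition,
        ratios=ratios,
        te_hits=te_hits,
        te_enrichment=te_enrichment,
        te_fraction=te_fraction,
        mirna_clean=mirna_clean,
        de_results=de_results,
        unassigned=unassigned,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _reads_mapped_to_reference(alignments, reference: ClusterSet):
    """Unique reads with at least one placement inside a reference cluster."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for c in reference:
        trees.setdefault(c.scaffold, IntervalTree()).addi(c.start, c.end)
    seen: dict[str, object] = {}
    for a in alignments:
        tree = trees.get(a.interval.scaffold)
        if tree is not None and tree.overlap(a.interval.start, a.interval.end):
            seen[a.read.sequence] = a.read
    return list(seen.values())


def _write_artifacts(result: PipelineResult, out: Path) -> dict[str, Path]:
    import dataclasses

    import yaml

    from .core_io import write_bed

    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    # every run carries its resolved parameter set
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(result.config), fh, sort_keys=True)

    write_bed(result.preliminary, out / "preliminary_reference.bed")
    write_bed(result.final, out / "final_reference.bed")
    result.matrix.to_tsv(out / "counts.tsv")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("cluster_id\tlabel\n")
        for cid, label in result.labels.items():
            fh.write(f"{cid}\t{label}\n")
    with open(out / "basestats.tsv", "w") as fh:
        fh.write("metric\tA\tC\tG\tU\n")
        for p in (1, 10):
            props = result.composition.proportions(p)
            fh.write(
                f"position_{p}\t{props['A']:.4f}\t{props['C']:.4f}\t"
                f"{props['G']:.4f}\t{props['U']:.4f}\n"
            )
        for v, r in result.ratios.items():
            fh.write(f"pathway_ratio_{v}\t{r.n_primary}\t{r.n_secondary}\t"
                     f"{'inf' if r.undefined_denominator else round(r.ratio, 4)}\t-\n")
    if not result.te_enrichment.empty:
        result.te_enrichment.to_csv(out / "te_report.tsv", sep="\t", index=False)
    else:
        (out / "te_report.tsv").write_text("no TE hits\n")
    results_to_frame(result.de_results).to_csv(out / "de.tsv", sep="\t", index=False)
    with open(out / "qc_report.tsv", "w") as fh:
        fh.write(f"preliminary_clusters\t{len(result.preliminary)}\n")
        fh.write(f"final_clusters\t{len(result.final)}\n")
        fh.write(f"te_hit_fraction\t{result.te_fraction:.4f}\n")
        fh.write(f"mirna_contamination_free\t{result.mirna_clean}\n")
        for lab, n in result.label_counts.items():
            fh.write(f"label_{lab}\t{n}\n")
        fh.write(f"seed\t{result.config.seed}\n")
        fh.write(f"depth\t{result.config.depth}\n")
        fh.write(f"merge_distance\t1000\n")

    for name in (
        "preliminary_reference.bed", "final_reference.bed", "counts.tsv",
        "labels.tsv", "basestats.tsv", "te_report.tsv", "de.tsv", "qc_report.tsv",
    ):
        artifacts[name] = out / name
    return artifacts
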
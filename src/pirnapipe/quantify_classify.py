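"""Quantification of all samples against the final reference and the
testis-only / soma-and-testis cluster classification.

A cluster is *testis-only* when its summed somatic read count stays below a
threshold equal to the number of somatic samples while the testis count
exceeds 50; it is *soma-and-testis* when both testis and at least one
somatic sample reach the expression floor (count >= 10). Testis-only takes
precedence, keeping the two sets disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_io import AlignmentRecord, ClusterSet, CollapsedRead, CountMatrix, SampleSheet
from .cluster_reference import count_reads_per_cluster
from .exact_mapper import GenomeIndex, map_reads

TESTIS_ONLY = "testis_only"
SOMA_AND_TESTIS = "soma_and_testis"
OTHER = "other"

# Somatic roles for classification. Ovary is germline and excluded from the
# somatic sum by default (configurable via somatic_roles).
DEFAULT_SOMATIC_ROLES = ("somatic_control", "tumor")


@dataclass
class ClassificationParams:
    somatic_sum_max: int | None = None  # default: number of somatic samples
    testis_min: int = 50
    expressed_min: int = 10
    somatic_roles: tuple[str, ...] = DEFAULT_SOMATIC_ROLES

    def __post_init__(self):
        if self.testis_min < 0 or self.expressed_min < 0:
            raise ValueError("thresholds must be >= 0")
        if self.somatic_sum_max is not None and self.somatic_sum_max < 0:
            raise ValueError("somatic_sum_max must be >= 0")


def quantify(
    sample_alignments: Mapping[str, Sequence[AlignmentRecord]],
    final_reference: ClusterSet,
    sheet: SampleSheet,
) -> tuple[CountMatrix, dict[str, float]]:
    """Assemble the clusters x samples count matrix from per-sample alignments.

    Placements outside every reference cluster are excluded and reported per
    sample as the second return value.
    """
    roles = sheet.roles
    for sid in sample_alignments:
        if sid not in roles:
            raise ValueError(f"sample {sid!r} absent from sample sheet")

    columns, unassigned = {}, {}
    for sid, alns in sample_alignments.items():
        counts, out = count_reads_per_cluster(alns, final_reference)
        columns[sid] = counts
        unassigned[sid] = out

    sample_ids = list(sample_alignments)
    table = pd.DataFrame(
        {sid: [columns[sid][cid] for cid in final_reference.ids] for sid in sample_ids},
        index=final_reference.ids,
    )
    matrix = CountMatrix(
        cluster_ids=final_reference.ids,
        sample_ids=sample_ids,
        counts=table,
        roles={sid: roles[sid] for sid in sample_ids},
    )
    return matrix, unassigned


def quantify_reads(
    sample_reads: Mapping[str, Sequence[CollapsedRead]],
    final_reference: ClusterSet,
    index: GenomeIndex,
    genome: Mapping[str, str],
    sheet: SampleSheet,
) -> tuple[CountMatrix, dict[str, float]]:
    """Map each sample's reads and quantify against the reference in one step."""
    alns = {
        sid: map_reads(reads, index, genome) for sid, reads in sample_reads.items()
    }
    return quantify(alns, final_reference, sheet)


def classify_clusters(
    matrix: CountMatrix, params: ClassificationParams | None = None
) -> dict[str, str]:
    """Label each cluster testis_only / soma_and_testis / other.

    testis_only iff sum(somatic) < somatic_sum_max AND testis > testis_min;
    else soma_and_testis iff testis >= expressed_min AND max(somatic) >=
    expressed_min; else other.
    """
    if params is None:
        params = ClassificationParams()
    testis_samples = matrix.samples_with_role("testis")
    if not testis_samples:
        raise ValueError("count matrix has no testis column")
    somatic_samples = [
        s for s in matrix.sample_ids if matrix.roles.get(s) in params.somatic_roles
    ]
    if not somatic_samples:
        raise ValueError("count matrix has no somatic columns")
    somatic_sum_max = (
        len(somatic_samples) if params.somatic_sum_max is None else params.somatic_sum_max
    )

    testis = matrix.counts[testis_samples].sum(axis=1)
    somatic = matrix.counts[somatic_samples]
    som_sum = somatic.sum(axis=1)
    som_max = somatic.max(axis=1)

    labels: dict[str, str] = {}
    for cid in matrix.cluster_ids:
        if som_sum[cid] < somatic_sum_max and testis[cid] > params.testis_min:
            labels[cid] = TESTIS_ONLY
        elif testis[cid] >= params.expressed_min and som_max[cid] >= params.expressed_min:
            labels[cid] = SOMA_AND_TESTIS
        else:
            labels[cid] = OTHER
    return labels


def classify_counts(
    testis: float,
    somatic: Sequence[float],
    somatic_sum_max: float,
    testis_min: float = 50,
    expressed_min: float = 10,
) -> str:
    """Classification rule on raw counts (used for grid checks and docs)."""
    if sum(somatic) < somatic_sum_max and testis > testis_min:
        return TESTIS_ONLY
    if testis >= expressed_min and max(somatic) >= expressed_min:
        return SOMA_AND_TESTIS
    return OTHER


@dataclass
class ExpressionSummary:
    label_counts: dict[str, int] = field(default_factory=dict)
    clusters_expressed_per_role: dict[str, int] = field(default_factory=dict)
    total: int = 0


def expression_accounting(
    matrix: CountMatrix, labels: Mapping[str, str], expressed_min: int = 10
) -> ExpressionSummary:
    """Cluster counts per label and per sample role (expressed = count >= floor)."""
    summary = ExpressionSummary(total=len(matrix.cluster_ids))
    for lab in (TESTIS_ONLY, SOMA_AND_TESTIS, OTHER):
        summary.label_counts[lab] = sum(1 for v in labels.values() if v == lab)
    if sum(summary.label_counts.values()) != summary.total:
        raise AssertionError("labels do not partition the cluster set")
    for role in sorted(set(matrix.roles.values())):
        cols = matrix.samples_with_role(role)
        expressed = (matrix.counts[cols] >= expressed_min).any(axis=1)
        summary.clusters_expressed_per_role[role] = int(expressed.sum())
    return summary
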
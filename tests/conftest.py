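import numpy as np
import pytest

from pirnapipe.core_io import CollapsedRead, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "seqs.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def random_genome(rng: np.random.Generator, length: int, scaffold="s1") -> dict[str, str]:
    return {scaffold: "".join(rng.choice(list("ACGT"), size=length))}


def make_read(seq: str, count: int = 1, sample: str = "x") -> CollapsedRead:
    return CollapsedRead(seq, count, sample)


def naive_scan(genome: dict[str, str], query: str) -> list[tuple[str, int, int, str]]:
    """Brute-force all-occurrence exact scan of a read on both strands."""
    from pirnapipe.core_io import reverse_complement

    hits = []
    for scaffold, seq in genome.items():
        for q, strand in ((query, "+"), (reverse_complement(query), "-")):
            start = seq.find(q)
            while start != -1:
                hits.append((scaffold, start, start + len(q), strand))
                start = seq.find(q, start + 1)
    return hits


def brute_force_merge(
    intervals: list[GenomicInterval], d: int
) -> list[tuple[str, int, int]]:
    """Transitive-closure merge oracle: O(n^2) pairwise gap graph + components."""
    import numpy as np
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    out = []
    scaffolds = sorted({iv.scaffold for iv in intervals})
    for scaffold in scaffolds:
        ivs = [iv for iv in intervals if iv.scaffold == scaffold]
        n = len(ivs)
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        # intervals i, j connected when gap(i, j) <= d (negative gap = overlap)
        gap = np.maximum(starts[None, :] - ends[:, None], starts[:, None] - ends[None, :])
        adj = csr_matrix(gap <= d)
        _, comp = connected_components(adj, directed=False)
        for c in np.unique(comp):
            sel = comp == c
            out.append((scaffold, int(starts[sel].min()), int(ends[sel].max())))
    return sorted(out)
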
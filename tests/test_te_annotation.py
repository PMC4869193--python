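import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnapipe.te_annotation import (
    TEEntry,
    TELibrary,
    fraction_clusters_with_hit,
    match_clusters_to_tes,
    mirna_contamination_flag,
    read_blast_tabular,
    te_class_enrichment,
    two_proportion_test,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, rate):
    out = list(seq)
    k = max(1, int(round(rate * len(seq))))
    for i in rng.choice(len(seq), size=k, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def best_local_identity(cluster: str, te: str, min_len: int = 50):
    """Exhaustive ungapped local-identity oracle over all offset pairs."""
    best = 0.0
    for ci in range(len(cluster)):
        for ti in range(len(te)):
            n = min(len(cluster) - ci, len(te) - ti)
            if n < min_len:
                continue
            a = np.frombuffer(cluster[ci : ci + n].encode(), dtype="S1")
            b = np.frombuffer(te[ti : ti + n].encode(), dtype="S1")
            matches = np.cumsum(a == b)
            lengths = np.arange(1, n + 1)
            ident = matches / lengths
            ok = lengths >= min_len
            if ok.any():
                best = max(best, float(ident[ok].max()))
    return best


class TestMatching:
    def test_exact_copy_full_identity(self, rng):
        te = _random_seq(rng, 200)
        cluster = _random_seq(rng, 300) + te + _random_seq(rng, 300)
        lib = TELibrary([TEEntry("te1", "LINE", te)])
        hits = match_clusters_to_tes({"c1": cluster}, lib)
        assert len(hits) == 1
        assert hits.iloc[0]["identity"] == 1.0
        assert hits.iloc[0]["length"] >= 200

    def test_heavily_mutated_copy_rejected(self, rng):
        te = _random_seq(rng, 200)
        # 15 % of sites mutated, evenly spread so no local window stays clean
        out = list(te)
        for i in np.linspace(0, 199, 30).astype(int):
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        diverged = "".join(out)
        cluster = _random_seq(rng, 300) + diverged + _random_seq(rng, 300)
        lib = TELibrary([TEEntry("te1", "LINE", te)])
        hits = match_clusters_to_tes({"c1": cluster}, lib, min_identity=0.90)
        # the exhaustive oracle confirms no >=90 % window of useful length exists
        assert best_local_identity(diverged, te) < 0.90
        assert hits.empty

    def test_threshold_monotone(self, rng):
        lib_entries, clusters = [], {}
        for i in range(6):
            te = _random_seq(rng, 200)
            lib_entries.append(TEEntry(f"te{i}", "DNA", te))
            clusters[f"c{i}"] = _random_seq(rng, 100) + _mutate(rng, te, 0.04) + _random_seq(rng, 100)
        lib = TELibrary(lib_entries)
        loose = match_clusters_to_tes(clusters, lib, min_identity=0.90)
        strict = match_clusters_to_tes(clusters, lib, min_identity=0.95)
        loose_pairs = set(zip(loose["cluster_id"], loose["te_id"]))
        strict_pairs = set(zip(strict["cluster_id"], strict["te_id"]))
        assert strict_pairs <= loose_pairs

    def test_reverse_complement_copy_found(self, rng):
        from pirnapipe.core_io import reverse_complement

        te = _random_seq(rng, 200)
        cluster = _random_seq(rng, 100) + reverse_complement(te) + _random_seq(rng, 100)
        lib = TELibrary([TEEntry("te1", "LTR", te)])
        assert len(match_clusters_to_tes({"c1": cluster}, lib)) == 1


class TestExternalEngine:
    def test_blast_tabular_threshold(self, tmp_path, rng):
        path = tmp_path / "hits.tab"
        path.write_text(
            "c1\tte1\t95.0\t200\t10\t0\t1\t200\t1\t200\t1e-50\t350\n"
            "c2\tte2\t85.0\t150\t22\t0\t1\t150\t1\t150\t1e-20\t180\n"
        )
        lib = TELibrary([TEEntry("te1", "LINE", "A" * 50), TEEntry("te2", "DNA", "C" * 50)])
        hits = match_clusters_to_tes({}, lib, engine="external", hits_path=path)
        assert list(hits["cluster_id"]) == ["c1"]
        assert hits.iloc[0]["te_class"] == "LINE"

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text("c1\tte1\t95.0\n")
        with pytest.raises(ValueError, match=":1"):
            read_blast_tabular(path)


class TestEnrichment:
    @staticmethod
    def _library(class_counts):
        entries = []
        for cls, n in class_counts.items():
            entries += [TEEntry(f"{cls}_{i}", cls, "ACGT" * 30) for i in range(n)]
        return TELibrary(entries)

    @staticmethod
    def _hits(te_ids, library):
        classes = {e.te_id: e.te_class for e in library.entries}
        return pd.DataFrame(
            {
                "cluster_id": [f"c{i}" for i in range(len(te_ids))],
                "te_id": te_ids,
                "te_class": [classes[t] for t in te_ids],
                "identity": 0.95,
                "length": 100,
                "score": 100.0,
            }
        )

    def test_matches_hand_computed_two_proportion_chi2(self):
        # 30/100 hit LINEs vs 10/100 library LINEs: Yates-corrected z-test
        stat, p = two_proportion_test(30, 100, 10, 100)
        p_pool = 40 / 200
        z = (abs(0.3 - 0.1) - (1 / 100)) / np.sqrt(p_pool * (1 - p_pool) * (2 / 100))
        assert stat == pytest.approx(z**2, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)

    def test_identical_proportions_not_flagged(self):
        lib = self._library({"LINE": 50, "DNA": 50})
        hits = self._hits([f"LINE_{i}" for i in range(10)] + [f"DNA_{i}" for i in range(10)], lib)
        table = te_class_enrichment(hits, lib)
        assert (table["p_value"] > 0.9).all()
        assert (table["flag"] == "").all()

    def test_distinct_te_unit(self):
        # many clusters hitting one TE count that TE once
        lib = self._library({"LINE": 5, "DNA": 5})
        hits = self._hits(["LINE_0"] * 4 + ["DNA_0"], lib)
        table = te_class_enrichment(hits, lib).set_index("te_class")
        assert table.loc["LINE", "n_hit"] == 1 and table.loc["DNA", "n_hit"] == 1

    def test_class_absent_from_library_skipped(self):
        lib = self._library({"LINE": 10})
        hits = self._hits(["LINE_0"], lib)
        hits.loc[len(hits)] = ["cX", "alien", "RC", 0.95, 100, 100.0]
        with pytest.warns(UserWarning, match="RC"):
            table = te_class_enrichment(hits, lib)
        assert "RC" not in set(table["te_class"])

    def test_chi2_close_to_permutation_test(self, rng):
        """The proportion test agrees with a label-permutation null at n >= 100."""
        lib = self._library({"LINE": 40, "DNA": 60})
        hit_ids = [f"LINE_{i}" for i in range(25)] + [f"DNA_{i}" for i in range(15)]
        hits = self._hits(hit_ids, lib)
        table = te_class_enrichment(hits, lib).set_index("te_class")
        p_chi = table.loc["LINE", "p_value"]

        labels = np.array([e.te_class for e in lib.entries])
        observed = abs(25 / 40 - 40 / 100)
        exceed = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            k = np.sum(perm[:40] == "LINE")  # 40 drawn as "hit" TEs
            if abs(k / 40 - 40 / 100) >= observed - 1e-12:
                exceed += 1
        p_perm = exceed / n_perm
        assert abs(p_chi - p_perm) < 0.05


class TestFractions:
    def test_every_cluster_hit(self):
        hits = pd.DataFrame({"cluster_id": ["a", "b"], "te_id": ["t", "t"],
                             "te_class": "DNA", "identity": 1.0, "length": 100,
                             "score": 1.0})
        assert fraction_clusters_with_hit(hits, ["a", "b"]) == 1.0

    def test_no_hits(self):
        empty = pd.DataFrame(columns=["cluster_id", "te_id", "te_class",
                                      "identity", "length", "score"])
        assert fraction_clusters_with_hit(empty, ["a", "b"]) == 0.0

    def test_planted_te_fraction_recovered(self):
        """A reference with 40 % TE-bearing clusters reports that fraction."""
        from pirnapipe.pipeline import run_pipeline

        res = run_pipeline(seed=3)
        planted = sum(1 for c in res.truth.clusters if c.te_id) / len(res.truth.clusters)
        assert res.te_fraction == pytest.approx(planted, abs=0.10)
        assert planted == pytest.approx(0.40, abs=1e-9)


def test_mirna_contamination_flag(rng):
    cluster = {"c1": _random_seq(rng, 500)}
    mirnas = {"m1": _random_seq(rng, 80)}
    assert mirna_contamination_flag(cluster, mirnas)
    dirty = {"c1": cluster["c1"][:200] + mirnas["m1"] + cluster["c1"][200:]}
    assert not mirna_contamination_flag(dirty, mirnas)
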
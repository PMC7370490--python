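"""Catalog deduplication, identity clustering and summary statistics."""

import math

import numpy as np
import pytest

from cassettescan.assembly import Cassette
from cassettescan.catalog import (
    CatalogEntry, cluster_by_identity, deduplicate, global_identity,
    summarize,
)
from cassettescan.orfs import OrfRecord
from cassettescan.scan import AttcHit


def mkcassette(contig, attc_start, orf_nt, sequences, strand="+"):
    """A cassette whose attC sequence comes from `sequences[contig]`."""
    site_len = 60
    hit = AttcHit(contig, strand, attc_start, attc_start + site_len,
                  (7, 1, 8, 29, 7, 1, 7), 5.0, 0.9)
    orf = OrfRecord(contig_id=contig, strand=strand, start=0, end=len(orf_nt),
                    frame=0, orf_score=1.0, nt_seq=orf_nt,
                    aa_seq="M" * (len(orf_nt) // 3 - 1))
    return Cassette(attc=hit, orfs=[orf], ordinal=1)


@pytest.fixture()
def sequences(rng):
    from cassettescan.simulate import _random_seq
    return {"c1": _random_seq(rng, 500, 0.5), "c2": _random_seq(rng, 500, 0.5)}


class TestDeduplicate:
    def test_identical_pairs_collapse(self, sequences):
        sequences["c2"] = sequences["c1"]  # same attC sequence on both contigs
        orf = "ATG" + "GCT" * 40 + "TAA"
        cassettes = [mkcassette("c1", 100, orf, sequences),
                     mkcassette("c2", 100, orf, sequences)]
        entries = deduplicate(cassettes, sequences)
        assert len(entries) == 1
        assert entries[0].contig_id == "c1"  # first occurrence kept

    def test_same_orf_different_attc_two_entries(self, sequences):
        orf = "ATG" + "GCT" * 40 + "TAA"
        cassettes = [mkcassette("c1", 100, orf, sequences),
                     mkcassette("c1", 300, orf, sequences)]
        assert len(deduplicate(cassettes, sequences)) == 2

    def test_empty_input(self):
        assert deduplicate([], {}) == []

    def test_orfless_cassettes_excluded(self, sequences):
        c = mkcassette("c1", 100, "ATGGCTTAA", sequences)
        c.orfs = []
        assert deduplicate([c], sequences) == []

    def test_idempotent_and_bounded(self, sequences, rng):
        from cassettescan.simulate import _random_seq
        cassettes = []
        for i in range(12):
            orf = "ATG" + _random_seq(rng, 90, 0.5) + "TAA"
            cassettes.append(mkcassette("c1", 50 * (i % 4), orf, sequences))
        entries = deduplicate(cassettes, sequences)
        assert len(entries) <= sum(len(c.orfs) for c in cassettes)
        # re-deduplicating the catalog's own pairs changes nothing
        again = {(e.attc_seq, e.orf_nt) for e in entries}
        assert len(again) == len(entries)


def transitive_greedy_oracle(proteins, cutoff):
    """All-vs-all identity matrix + greedy centroid walk (independent)."""
    order = sorted(proteins, key=lambda p: (-len(p[1]), p[1], p[0]))
    ident = {}
    for i, (pa, sa) in enumerate(order):
        for j, (pb, sb) in enumerate(order):
            if i < j:
                ident[(pa, pb)] = ident[(pb, pa)] = global_identity(sa, sb)
    clusters = []
    centroids = []
    for pid, seq in order:
        for ci, cid in enumerate(centroids):
            if ident[(pid, cid)] >= cutoff:
                clusters[ci].append(pid)
                break
        else:
            centroids.append(pid)
            clusters.append([pid])
    return clusters


class TestClusterByIdentity:
    BASE = "MKVLAGTSERLIPNQWHDYF"

    def toy_set(self):
        a = self.BASE
        b = a[:19] + "W"                    # identity 0.95 to a
        c = a[:10] + "AAAAAAAAAA"           # ~0.50-0.55 to a
        d = "WWCCHHGGPPRRSSTTVVYY"
        e = d[:17] + "AAA"                  # 0.85 to d
        f = "NNNNNDDDDDEEEEEQQQQQ"
        return [("a", a), ("b", b), ("c", c), ("d", d), ("e", e), ("f", f)]

    def test_identical_sequences_one_cluster(self):
        proteins = [(f"p{i}", "MKVLAGTSER") for i in range(5)]
        res = cluster_by_identity(proteins, 0.97)
        assert res.n_clusters == 1
        assert res.n_singletons == 0
        assert res.max_cluster_size == 5

    @pytest.mark.parametrize("cutoff", [0.97, 0.9, 0.7, 0.5])
    def test_toy_set_matches_all_vs_all_oracle(self, cutoff):
        proteins = self.toy_set()
        res = cluster_by_identity(proteins, cutoff)
        oracle = transitive_greedy_oracle(proteins, cutoff)
        assert sorted(map(sorted, res.clusters)) == sorted(map(sorted, oracle))

    def test_cluster_count_monotone_in_cutoff(self, rng):
        from cassettescan.simulate import _random_seq
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        proteins = []
        for i in range(25):
            n = int(rng.integers(30, 80))
            proteins.append((f"p{i}", "".join(
                alphabet[int(k)] for k in rng.integers(0, 20, size=n))))
        counts = [cluster_by_identity(proteins, c).n_clusters
                  for c in (0.97, 0.70, 0.50)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_partition_property(self):
        proteins = self.toy_set()
        res = cluster_by_identity(proteins, 0.7)
        members = sorted(m for c in res.clusters for m in c)
        assert members == sorted(p[0] for p in proteins)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cluster_by_identity([("a", "MKV")], 0.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_by_identity([("a", "")], 0.9)


def test_global_identity_basics():
    assert global_identity("MKVLAG", "MKVLAG") == 1.0
    assert global_identity("MKVLAG", "MKVLAW") == pytest.approx(5 / 6)
    # end gaps count against identity
    assert global_identity("MKV", "MKVLAGTSER") <= 0.3


def mkentry(i, orf_nt, attc="A" * 60):
    return CatalogEntry(entry_id=f"E{i}", attc_seq=attc, orf_nt=orf_nt,
                        orf_aa="M" * (len(orf_nt) // 3 - 1), contig_id="c",
                        orf_start=0, orf_end=len(orf_nt), strand="+")


class TestSummarize:
    def test_all_gc_sequence(self):
        e = mkentry(0, "GGCC" * 30)
        assert e.gc == 1.0

    def test_median_order_statistic(self):
        entries = [mkentry(i, "A" * n) for i, n in enumerate((300, 402, 900))]
        s = summarize(entries, total_bases_scanned=10**6, n_attc=3)
        assert s["length_median"] == 402

    def test_table_row_rounding(self):
        # 5,377 sites in 13 Gb -> 0.41 copies/Mb, printing as 0.4
        s = summarize([], total_bases_scanned=13 * 10**9, n_attc=5377)
        assert s["attc_copies_per_mb"] == pytest.approx(0.4136, abs=1e-3)
        assert f"{s['attc_copies_per_mb']:.1f}" == "0.4"

    def test_abundance_scale_invariance(self):
        a = summarize([], 10**7, 25)["attc_copies_per_mb"]
        b = summarize([], 2 * 10**7, 50)["attc_copies_per_mb"]
        assert a == pytest.approx(b)

    def test_empty_catalog_flagged(self):
        s = summarize([], 1000, 0)
        assert s["n_entries"] == 0
        assert not s["medians_defined"]
        assert math.isnan(s["length_median"])

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            summarize([], 0, 0)
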
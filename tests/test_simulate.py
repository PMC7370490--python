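"""Synthetic metagenome generation, shuffling and evaluation."""

from collections import Counter

import numpy as np
import pytest

from cassettescan.orfs import OrfRecord
from cassettescan.scan import AttcHit
from cassettescan.simulate import (
    EvalResult, SimParams, SimTruth, TruthAttc, TruthOrf,
    dinucleotide_shuffle, evaluate, make_attc_site, shuffle_negative,
    simulate_metagenome,
)

SMALL = dict(n_contigs=6, n_arrays=6, contig_len=(12000, 15000))


class TestSimulateMetagenome:
    def test_deterministic_given_seed(self):
        p1 = SimParams(seed=5, **SMALL)
        p2 = SimParams(seed=5, **SMALL)
        r1, t1 = simulate_metagenome(p1)
        r2, t2 = simulate_metagenome(p2)
        assert r1 == r2
        assert t1 == t2

    def test_different_seeds_differ(self):
        r1, _ = simulate_metagenome(SimParams(seed=5, **SMALL))
        r2, _ = simulate_metagenome(SimParams(seed=6, **SMALL))
        assert r1 != r2

    def test_bookkeeping_fixed_cassette_count(self):
        params = SimParams(seed=2, n_contigs=10, n_arrays=10,
                           cassettes_per_array=(3, 3))
        _, truth = simulate_metagenome(params)
        assert len(truth.attcs) == 30
        assert len(truth.orfs) >= 30
        assert truth.n_arrays() == 10

    def test_site_lengths_within_bounds(self):
        _, truth = simulate_metagenome(SimParams(seed=3, **SMALL))
        for t in truth.attcs:
            assert 55 <= t.end - t.start <= 141
            assert sum(t.segment_lengths) == t.end - t.start

    def test_truth_elements_inside_contigs(self):
        recs, truth = simulate_metagenome(SimParams(seed=4, **SMALL))
        lengths = {rid: len(seq) for rid, seq in recs}
        for t in truth.attcs + truth.orfs:
            assert 0 <= t.start < t.end <= lengths[t.contig_id]

    def test_consecutive_gaps_within_proximity_limit(self):
        _, truth = simulate_metagenome(SimParams(seed=4, **SMALL))
        per_array = {}
        for t in truth.attcs:
            per_array.setdefault((t.contig_id, t.array_id), []).append(t)
        for sites in per_array.values():
            sites.sort(key=lambda t: t.start)
            assert len(sites) >= 2
            for a, b in zip(sites, sites[1:]):
                assert b.start - a.end <= 4000

    def test_contig_too_short_raises(self):
        params = SimParams(seed=1, n_contigs=1, n_arrays=1,
                           contig_len=(3000, 3000),
                           cassettes_per_array=(8, 8))
        with pytest.raises((ValueError, RuntimeError), match="too short"):
            simulate_metagenome(params)

    def test_mutation_zero_sites_exactly_consensus_paired(self):
        from cassettescan.structure import pairing_score
        recs, truth = simulate_metagenome(
            SimParams(seed=8, motif_mut_rate=0.0, **SMALL))
        seqs = dict(recs)
        for t in truth.attcs[:20]:
            hit = AttcHit(t.contig_id, t.strand, t.start, t.end,
                          t.segment_lengths, 1.0)
            assert pairing_score(hit, seqs[t.contig_id]).structure_score == 1.0


class TestShuffle:
    def test_length_preserved(self, rng):
        from cassettescan.simulate import _random_seq
        seq = _random_seq(rng, 5000, 0.4)
        assert len(dinucleotide_shuffle(seq, rng)) == len(seq)

    def test_dinucleotide_counts_preserved(self, rng):
        from cassettescan.simulate import _random_seq
        for _ in range(5):
            seq = _random_seq(rng, 3000, float(rng.uniform(0.3, 0.7)))
            shuf = dinucleotide_shuffle(seq, rng)
            assert Counter(zip(shuf, shuf[1:])) == Counter(zip(seq, seq[1:]))
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_deterministic_by_seed(self):
        recs = [("a", "ACGTACGGTTACGATCG" * 100)]
        s1 = shuffle_negative(recs, seed=9)
        s2 = shuffle_negative(recs, seed=9)
        s3 = shuffle_negative(recs, seed=10)
        assert s1 == s2
        assert s1 != s3
        assert s1[0][0] == "a_shuffled"

    def test_shuffle_destroys_planted_sites(self, trained_model):
        from cassettescan import scan_sequence
        from cassettescan.simulate import _reciprocal_overlap
        recs, truth = simulate_metagenome(SimParams(seed=12, **SMALL))
        shuffled = dict((rid.replace("_shuffled", ""), seq)
                        for rid, seq in shuffle_negative(recs, seed=12))
        survived = 0
        for t in truth.attcs:
            hits = []
            seq = shuffled[t.contig_id]
            window = seq[max(0, t.start - 200):t.end + 200]
            hits = scan_sequence((t.contig_id, window), trained_model)
            if any(h.hmm_score > 5 and h.strand == t.strand and
                   _reciprocal_overlap((h.start + max(0, t.start - 200),
                                        h.end + max(0, t.start - 200)),
                                       (t.start, t.end)) >= 0.5 for h in hits):
                survived += 1
        assert survived <= 0.01 * len(truth.attcs) + 1


def attc(contig, strand, start, end):
    d = end - start
    return AttcHit(contig, strand, start, end, (7, 1, 8, d - 31, 7, 1, 7),
                   5.0, 0.9)


def torf(contig, strand, start, end, array=0, ordinal=1):
    return TruthOrf(contig, strand, start, end, array, ordinal)


def tattc(contig, strand, start, end, array=0, ordinal=1):
    return TruthAttc(contig, strand, start, end, (7, 1, 8, end - start - 31,
                                                  7, 1, 7), array, ordinal)


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = SimTruth(attcs=[tattc("c", "+", 100, 160),
                                tattc("c", "+", 1000, 1070, ordinal=2)],
                         orfs=[torf("c", "+", 300, 600)])
        preds = [attc("c", "+", 100, 160), attc("c", "+", 1000, 1070)]
        orfs = [OrfRecord("c", "+", 300, 600, 0, 1.0, "A" * 300, "M" * 99)]
        ev = evaluate(preds, orfs, truth)
        assert ev.attc_sensitivity == 1.0
        assert ev.attc_false_positives == 0
        assert ev.orf_sensitivity == 1.0
        assert ev.orf_false_positives == 0
        assert ev.attc_boundary_mean == 0.0

    def test_empty_predictions(self):
        truth = SimTruth(attcs=[tattc("c", "+", 100, 160)],
                         orfs=[torf("c", "+", 300, 600)])
        ev = evaluate([], [], truth)
        assert ev.attc_sensitivity == 0.0
        assert ev.orf_sensitivity == 0.0

    def test_hand_built_confusion(self):
        # 2 of 4 truth sites overlapped; 1 prediction matches nothing
        truth = SimTruth(attcs=[tattc("c", "+", 0, 60),
                                tattc("c", "+", 500, 560),
                                tattc("c", "+", 1000, 1060),
                                tattc("c", "+", 1500, 1560)])
        preds = [attc("c", "+", 0, 60), attc("c", "+", 505, 565),
                 attc("c", "+", 3000, 3060)]
        ev = evaluate(preds, [], truth)
        assert ev.attc_sensitivity == 0.5
        assert ev.attc_false_positives == 1

    def test_strand_mismatch_not_detected(self):
        truth = SimTruth(attcs=[tattc("c", "+", 0, 60)])
        ev = evaluate([attc("c", "-", 0, 60)], [], truth)
        assert ev.attc_sensitivity == 0.0
        assert ev.attc_false_positives == 1

    def test_boundary_tolerance_applies(self):
        truth = SimTruth(attcs=[tattc("c", "+", 100, 160)])
        shifted = attc("c", "+", 115, 175)
        assert evaluate([shifted], [], truth, boundary_tol=10).attc_detected == 0
        assert evaluate([shifted], [], truth, boundary_tol=20).attc_detected == 1
        assert evaluate([shifted], [], truth,
                        boundary_tol=None).attc_detected == 1
        # a loosely-matching prediction is still not a false positive
        assert evaluate([shifted], [], truth).attc_false_positives == 0


def test_make_attc_site_complementary_before_mutation(rng):
    from cassettescan.structure import pairing_score
    for _ in range(10):
        site, lengths = make_attc_site(rng, 0.5, 0.0)
        assert 55 <= len(site) <= 141
        hit = AttcHit("c", "+", 0, len(site), lengths, 1.0)
        assert pairing_score(hit, site).structure_score == 1.0
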
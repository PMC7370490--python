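"""Generalized-Viterbi site detection: oracle equivalence and scanning."""

import math

import numpy as np
import pytest

from cassettescan.model import CONSENSUS_R1, IUPAC, reverse_complement
from cassettescan.scan import (
    AttcHit, SequenceAlphabetError, scan_sequence, viterbi_best_site,
)
from cassettescan.simulate import _random_seq, make_attc_site

BASE_INDEX = {c: i for i, c in enumerate("ACGT")}


def brute_force_best(window, model, tol=1e-12):
    """Exhaustive enumeration over all admissible duration triples.

    Independent of the scanner: plain Python loops and per-position
    products.  Returns (best_score, set of co-optimal duration triples).
    """
    def motif_logodds(pwm, seq):
        total = 0.0
        for i, c in enumerate(seq):
            bases = IUPAC[c]
            p = sum(pwm[i][BASE_INDEX[b]] for b in bases) / len(bases)
            total += math.log(p) - math.log(0.25)
        return total

    def comp_logodds(seq):
        total = 0.0
        for c in seq:
            bases = IUPAC[c]
            p = sum(model.region_composition[BASE_INDEX[b]] for b in bases) / len(bases)
            total += math.log(p) - math.log(0.25)
        return total

    L = len(window)
    best, argmax = None, set()
    for d1 in range(1, 11):
        for dl in range(14, 103):
            for d2 in range(1, 11):
                total_len = 29 + d1 + dl + d2
                if total_len > L or not (55 <= total_len <= 141):
                    continue
                sc = (motif_logodds(model.pwm_R2, window[0:7])
                      + math.log(model.dur_spacer1[d1 - 1])
                      + comp_logodds(window[7:7 + d1])
                      + motif_logodds(model.pwm_L2, window[7 + d1:15 + d1])
                      + math.log(model.dur_loop[dl - 14])
                      + comp_logodds(window[15 + d1:15 + d1 + dl])
                      + motif_logodds(model.pwm_L1,
                                      window[15 + d1 + dl:22 + d1 + dl])
                      + math.log(model.dur_spacer2[d2 - 1])
                      + comp_logodds(window[22 + d1 + dl:22 + d1 + dl + d2])
                      + motif_logodds(model.pwm_R1,
                                      window[22 + d1 + dl + d2:29 + d1 + dl + d2]))
                if best is None or sc > best + tol:
                    best, argmax = sc, {(d1, dl, d2)}
                elif abs(sc - best) <= tol:
                    argmax.add((d1, dl, d2))
    return best, argmax


def assert_matches_oracle(window, model, tables=None):
    result = viterbi_best_site(window, model, tables)
    best, argmax = brute_force_best(window, model)
    if best is None:
        assert result is None
        return
    lengths, score = result
    assert score == pytest.approx(best, abs=1e-9)
    assert (lengths[1], lengths[3], lengths[5]) in argmax


class TestViterbi:
    def test_consensus_site_boundaries_recovered(self, default_model, rng):
        # exact-consensus 55 nt site with spacer1=5, loop=16, spacer2=5
        r1 = "ACCTAAC"  # realization of RYYYAAC
        l1 = "GTTTAAC"
        l2 = reverse_complement(l1)[:3] + "G" + reverse_complement(l1)[3:]
        site = (reverse_complement(r1) + _random_seq(rng, 5, 0.5) + l2
                + _random_seq(rng, 16, 0.5) + l1 + _random_seq(rng, 5, 0.5) + r1)
        window = site + _random_seq(rng, 5, 0.5)
        lengths, score = viterbi_best_site(window, default_model)
        assert lengths == (7, 5, 8, 16, 7, 5, 7)

    def test_window_of_a_runs_returns_none(self, default_model):
        assert viterbi_best_site("A" * 50, default_model) is None

    def test_short_window_below_min_len(self, default_model):
        assert viterbi_best_site("ACGT" * 13, default_model) is None  # 52 nt

    @pytest.mark.parametrize("length", [55, 80, 111, 141])
    def test_matches_brute_force_on_random_windows(self, default_model,
                                                   default_tables, rng, length):
        for _ in range(5):
            window = _random_seq(rng, length, 0.5)
            assert_matches_oracle(window, default_model, default_tables)

    def test_matches_brute_force_with_trained_model(self, trained_model, rng):
        for _ in range(5):
            window = _random_seq(rng, int(rng.integers(55, 142)), 0.4)
            assert_matches_oracle(window, trained_model)

    def test_exact_site_product_form_score(self, default_model, rng):
        # score of a planted site equals the independent product-form sum
        site, lengths = make_attc_site(rng, 0.5, 0.0)
        got_lengths, score = viterbi_best_site(site, default_model)
        best, _ = brute_force_best(site, default_model)
        assert score == pytest.approx(best, abs=1e-9)

    def test_ambiguity_codes_accepted(self, default_model, rng):
        site, _ = make_attc_site(rng, 0.5, 0.0)
        window = site[:20] + "N" + site[21:]
        assert viterbi_best_site(window, default_model) is not None


class TestScan:
    def test_planted_site_recovered_at_interval(self, trained_model, rng):
        site, lengths = make_attc_site(rng, 0.5, 0.0)
        contig = _random_seq(rng, 400, 0.5) + site + _random_seq(rng, 400, 0.5)
        hits = scan_sequence(("c", contig), trained_model)
        top = max(hits, key=lambda h: h.hmm_score)
        assert (top.strand, top.start, top.end) == ("+", 400, 400 + len(site))
        assert top.segment_lengths == lengths

    def test_all_hits_above_threshold(self, trained_model, rng):
        contig = _random_seq(rng, 20000, 0.5)
        for thr in (0.0, 3.0):
            hits = scan_sequence(("c", contig), trained_model, thr)
            assert all(h.hmm_score > thr for h in hits)

    def test_strand_symmetry(self, trained_model, rng):
        site, _ = make_attc_site(rng, 0.5, 0.0)
        contig = _random_seq(rng, 800, 0.5) + site + _random_seq(rng, 500, 0.5)
        L = len(contig)
        fwd = scan_sequence(("c", contig), trained_model)
        rev = scan_sequence(("c", reverse_complement(contig)), trained_model)
        mirror = sorted((("+-"["+-".index(h.strand) ^ 1]), L - h.end, L - h.start,
                         round(h.hmm_score, 6)) for h in rev)
        orig = sorted((h.strand, h.start, h.end, round(h.hmm_score, 6))
                      for h in fwd)
        assert mirror == orig

    def test_same_strand_hits_non_overlapping(self, trained_model, rng):
        contig = _random_seq(rng, 30000, 0.5)
        hits = scan_sequence(("c", contig), trained_model)
        for strand in "+-":
            sh = sorted([h for h in hits if h.strand == strand],
                        key=lambda h: h.start)
            for a, b in zip(sh, sh[1:]):
                assert a.end <= b.start

    def test_segmentation_tiles_site(self, trained_model, rng):
        site, _ = make_attc_site(rng, 0.5, 0.05)
        contig = _random_seq(rng, 200, 0.5) + site + _random_seq(rng, 200, 0.5)
        for hit in scan_sequence(("c", contig), trained_model):
            assert sum(hit.segment_lengths) == hit.length
            assert 55 <= hit.length <= 141
            segs = hit.segments()
            assert segs[0][1] == 0 and segs[-1][2] == hit.length
            for (_, _, e1), (_, s2, _) in zip(segs, segs[1:]):
                assert e1 == s2

    def test_empty_sequence_returns_empty(self, trained_model):
        assert scan_sequence(("c", ""), trained_model) == []

    def test_invalid_character_names_position(self, trained_model):
        with pytest.raises(SequenceAlphabetError, match="position 3"):
            scan_sequence(("c", "ACG!ACGT" * 20), trained_model)

    def test_minus_strand_coordinates_projected(self, trained_model, rng):
        site, _ = make_attc_site(rng, 0.5, 0.0)
        planted = reverse_complement(site)
        contig = _random_seq(rng, 300, 0.5) + planted + _random_seq(rng, 300, 0.5)
        hits = scan_sequence(("c", contig), trained_model)
        top = max(hits, key=lambda h: h.hmm_score)
        assert top.strand == "-"
        assert (top.start, top.end) == (300, 300 + len(site))
        # site_sequence returns the hairpin orientation
        assert top.site_sequence(contig) == site
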
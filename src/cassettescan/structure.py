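"""Hairpin secondary-structure validation of candidate attC sites.

The bottom strand of a genuine attC site folds back on itself so that R''
pairs with R' and L'' pairs with L'.  This module scores that fold
directly: it counts complementary positions between R'' and the reverse of
R', and between L'' and the reverse of L' under the best single-bulge
alignment (L'' is one nucleotide longer than L'; its extra-helical
position is left unpaired).  G-U wobble pairs count as complementary,
since they stabilize real RNA/ssDNA hairpins.

The fraction of complementary pairs over the 14 scored positions is the
structure score; candidate sites below a calibrated threshold (default
0.75) are rejected.  Because a palindrome matches on both strands,
overlapping cross-strand duplicates are resolved by keeping the
highest-scoring hit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import LEN_L1, LEN_L2, LEN_R1, LEN_R2
from .scan import AttcHit

#: base pairs counted as complementary (Watson-Crick plus G.U/T wobble)
COMPLEMENTARY = {
    ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
    ("G", "T"), ("T", "G"),
}


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in COMPLEMENTARY


@dataclass
class PairingReport:
    """Complementarity of the two motif pairs of one candidate site."""

    r_pairs: list[bool]        # R'' position i vs R' position (7-1-i)
    l_pairs: list[bool]        # best single-bulge alignment of L'' vs L'
    bulge_index: int           # L'' position left unpaired
    structure_score: float     # complementary pairs / scored pairs, in [0,1]

    @property
    def n_scored(self) -> int:
        return len(self.r_pairs) + len(self.l_pairs)


def _best_bulge_alignment(l2: str, l1: str) -> tuple[list[bool], int]:
    """Best pairing of L''(8) against reverse(L'(7)) over all 8 bulge choices.

    Removing position ``b`` from L'' leaves 7 positions; position i of the
    remainder pairs with position (7-1-i) of L'.  Ties prefer the smallest
    bulge index.
    """
    assert len(l2) == LEN_L2 and len(l1) == LEN_L1
    best_flags: list[bool] = []
    best_b = 0
    best_n = -1
    for b in range(LEN_L2):
        reduced = l2[:b] + l2[b + 1:]
        flags = [_is_pair(reduced[i], l1[LEN_L1 - 1 - i]) for i in range(LEN_L1)]
        n = sum(flags)
        if n > best_n:
            best_flags, best_b, best_n = flags, b, n
    return best_flags, best_b


def pairing_score(hit: AttcHit, sequence: str) -> PairingReport:
    """Score the hairpin fold of a candidate site.

    ``sequence`` is the top strand of the hit's contig; the site is
    re-oriented to the scanned strand before pairing.  Non-ACGT letters
    never count as complementary.
    """
    if hit.start < 0 or hit.end > len(sequence):
        raise ValueError(
            f"hit {hit.contig_id}:{hit.start}-{hit.end} lies outside its "
            f"{len(sequence)} nt sequence")
    site = hit.site_sequence(sequence)
    if len(site) != sum(hit.segment_lengths):
        raise ValueError(
            f"hit {hit.contig_id}:{hit.start}-{hit.end}: segmentation does not "
            f"tile the site")
    segs = {name: site[a:b] for name, a, b in hit.segments()}
    r2, r1 = segs["R2"], segs["R1"]
    r_flags = [_is_pair(r2[i], r1[LEN_R1 - 1 - i]) for i in range(LEN_R2)]
    l_flags, bulge = _best_bulge_alignment(segs["L2"], segs["L1"])
    n_scored = len(r_flags) + len(l_flags)
    score = (sum(r_flags) + sum(l_flags)) / n_scored
    return PairingReport(r_pairs=r_flags, l_pairs=l_flags,
                         bulge_index=bulge, structure_score=score)


def validate_hits(hits: list[AttcHit], record, min_structure: float = 0.75,
                  external_scores: dict | None = None) -> list[AttcHit]:
    """Annotate hits with structure scores and keep those >= threshold.

    ``record`` is the contig (SeqRecord, (id, seq) pair or string).  If
    ``external_scores`` maps ``(contig_id, start, end, strand)`` to a score
    (e.g. from an external covariance-model run), it replaces the built-in
    pairing score and ``min_structure`` applies to it instead.
    """
    from .scan import _record_parts
    _, seq = _record_parts(record)
    kept = []
    for hit in hits:
        if external_scores is not None:
            key = (hit.contig_id, hit.start, hit.end, hit.strand)
            score = external_scores.get(key)
            if score is None:
                continue
            hit.structure_score = float(score)
        else:
            hit.structure_score = pairing_score(hit, seq).structure_score
        if hit.structure_score >= min_structure:
            kept.append(hit)
    return kept


def _sort_key(hit: AttcHit):
    struct = hit.structure_score if hit.structure_score is not None else float("-inf")
    # higher (structure, hmm) first; ties prefer + strand, then leftmost
    return (-struct, -hit.hmm_score, 0 if hit.strand == "+" else 1,
            hit.start, hit.end)


def resolve_overlaps(hits: list[AttcHit]) -> list[AttcHit]:
    """Keep the best hit among any set of overlapping top-strand intervals.

    Overlap means >= 1 shared top-strand position, regardless of strand.
    The winner has the lexicographically highest (structure_score,
    hmm_score); exact ties prefer the + strand, then the leftmost start.
    Output is pairwise non-overlapping and sorted by position; the
    operation is idempotent.
    """
    kept: list[AttcHit] = []
    for hit in sorted(hits, key=_sort_key):
        if not any(hit.overlaps(k) for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def read_external_scores(path) -> dict:
    """Read a TSV of external per-hit scores: contig, start, end, strand, score."""
    scores = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("contig", "contig_id"):
                continue
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 columns "
                    f"(contig, start, end, strand, score)")
            scores[(parts[0], int(parts[1]), int(parts[2]), parts[3])] = float(parts[4])
    return scores
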
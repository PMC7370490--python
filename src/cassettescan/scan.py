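"""Detection of candidate attC sites by generalized-Viterbi scanning.

The site grammar along the scanned strand is

    R''(7) - spacer1(1..10) - L''(8) - loop(14..102) - L'(7) - spacer2(1..10) - R'(7)

with the total length constrained to the model's site-length bounds
(55-141 nt by default).  For a window anchored at a fixed start,
:func:`viterbi_best_site` maximizes the log-odds score over all admissible
duration triples.  :func:`scan_sequence` sweeps every start position on
both strands: a single-precision dynamic-programming sweep computes, per
start, the best score over duration combinations relaxing only the joint
site-length bound, which upper-bounds the constrained optimum and gates
the exact parse to the rare candidate starts; accepted parses are then
re-scored in double precision from the closed-form sum of their terms.

Scores are natural-log odds against the model's 0-order background:
per-position motif log-odds, plus the duration log-probabilities of the
three variable regions, plus the composition log-odds of the variable
region residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AttcModel, BASES, IUPAC, LEN_L1, LEN_L2, LEN_R1, LEN_R2, MOTIF_TOTAL,
)

SEGMENT_NAMES = ("R2", "spacer1", "L2", "loop", "L1", "spacer2", "R1")

#: integer code per IUPAC letter, in a fixed order; used to index lookup tables
_CODE_ORDER = "ACGTRYSWKMBDHVN"
_CODE_INDEX = {c: i for i, c in enumerate(_CODE_ORDER)}
_CODE_INDEX["U"] = _CODE_INDEX["T"]

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _c, _i in _CODE_INDEX.items():
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i

#: complement code index for reverse complementing encoded sequence
_COMP = np.array([_CODE_INDEX[c] for c in "TGCAYRSWMKVHDBN"], dtype=np.int8)


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a non-IUPAC character."""


def encode_sequence(seq: str, name: str = "sequence") -> np.ndarray:
    """Encode to int8 codes (0..14); raise naming the first bad position."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise SequenceAlphabetError(
            f"{name}: invalid nucleotide {seq[pos]!r} at position {pos}")
    return codes


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def _code_prob(dist: np.ndarray) -> np.ndarray:
    """Mean emission probability of each IUPAC code under a base distribution."""
    out = np.empty(len(_CODE_ORDER))
    for c, i in ((c, _CODE_INDEX[c]) for c in _CODE_ORDER):
        idx = [BASES.index(b) for b in IUPAC[c]]
        out[i] = float(np.mean(dist[idx]))
    return out


class _DurationGrid:
    """Flattened enumeration of all (spacer1, loop, spacer2) triples.

    Enumeration order is lexicographic ascending, which fixes the
    tie-break of :func:`viterbi_best_site` to the smallest triple.
    """

    def __init__(self, model: AttcModel, ld_s1, ld_loop, ld_s2):
        s_lo, s_hi = model.spacer_support
        l_lo, l_hi = model.loop_support
        d1 = np.arange(s_lo, s_hi + 1)
        dl = np.arange(l_lo, l_hi + 1)
        d2 = np.arange(s_lo, s_hi + 1)
        D1, DL, D2 = (a.ravel() for a in np.meshgrid(d1, dl, d2, indexing="ij"))
        self.d1, self.dl, self.d2 = D1, DL, D2
        self.total = MOTIF_TOTAL + D1 + DL + D2
        self.base_feasible = ((self.total >= model.min_site_len)
                              & (self.total <= model.max_site_len))
        self.ld_sum = (ld_s1[D1 - s_lo] + ld_loop[DL - l_lo] + ld_s2[D2 - s_lo])
        # segment start offsets per triple
        self.p_sp1 = np.full_like(D1, LEN_R2)
        self.p_l2 = LEN_R2 + D1
        self.p_loop = self.p_l2 + LEN_L2
        self.p_l1 = self.p_loop + DL
        self.p_s2 = self.p_l1 + LEN_L1
        self.p_r1 = self.p_s2 + D2


@dataclass
class ScoringTables:
    """Per-code log-odds lookup tables derived from an :class:`AttcModel`."""

    motif_lo: dict   # name -> (motif_len, 15) float64
    comp_lo: np.ndarray
    ld_s1: np.ndarray
    ld_loop: np.ndarray
    ld_s2: np.ndarray
    model: AttcModel
    motif_lo32: dict = field(default_factory=dict)
    comp_lo32: np.ndarray | None = None
    _grid: _DurationGrid | None = None

    @classmethod
    def from_model(cls, model: AttcModel) -> "ScoringTables":
        bg = _code_prob(model.background)
        motif_lo = {}
        for name, pwm in (("R2", model.pwm_R2), ("L2", model.pwm_L2),
                          ("L1", model.pwm_L1), ("R1", model.pwm_R1)):
            tab = np.empty((pwm.shape[0], len(_CODE_ORDER)))
            for i in range(pwm.shape[0]):
                p = _code_prob(pwm[i])
                with np.errstate(divide="ignore"):
                    tab[i] = np.log(p) - np.log(bg)
            # N (and any code averaging to background) scores 0 by construction
            motif_lo[name] = tab
        comp = _code_prob(model.region_composition)
        with np.errstate(divide="ignore"):
            comp_lo = np.log(comp) - np.log(bg)
        tables = cls(
            motif_lo=motif_lo,
            comp_lo=comp_lo,
            ld_s1=model.duration_logpmf("spacer1"),
            ld_loop=model.duration_logpmf("loop"),
            ld_s2=model.duration_logpmf("spacer2"),
            model=model,
        )
        tables.motif_lo32 = {k: v.astype(np.float32) for k, v in motif_lo.items()}
        tables.comp_lo32 = comp_lo.astype(np.float32)
        return tables

    def grid(self) -> _DurationGrid:
        if self._grid is None:
            self._grid = _DurationGrid(self.model, self.ld_s1, self.ld_loop,
                                       self.ld_s2)
        return self._grid

    @property
    def flat_composition(self) -> bool:
        return bool(np.all(self.comp_lo == 0.0))


@dataclass
class AttcHit:
    """A located candidate attC site.

    ``start``/``end`` are 0-based half-open coordinates on the input top
    strand regardless of ``strand``; ``segment_lengths`` are the seven
    segment lengths in grammar order along the *scanned* strand.
    """

    contig_id: str
    strand: str
    start: int
    end: int
    segment_lengths: tuple[int, int, int, int, int, int, int]
    hmm_score: float
    structure_score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def segments(self) -> list[tuple[str, int, int]]:
        """Seven (name, local_start, local_end) intervals tiling [0, length)."""
        out = []
        pos = 0
        for name, ln in zip(SEGMENT_NAMES, self.segment_lengths):
            out.append((name, pos, pos + ln))
            pos += ln
        return out

    def site_sequence(self, top_strand_seq: str) -> str:
        """Site sequence in scanned-strand (hairpin) orientation."""
        from .model import reverse_complement
        chunk = top_strand_seq[self.start:self.end].upper()
        return chunk if self.strand == "+" else reverse_complement(chunk)

    def overlaps(self, other: "AttcHit") -> bool:
        return self.start < other.end and other.start < self.end


def _motif_positions(codes: np.ndarray, tab: np.ndarray) -> np.ndarray:
    """Motif log-odds score at every start position; -inf where it overruns."""
    L = codes.size
    w = tab.shape[0]
    m = np.full(L + 1, -np.inf, dtype=tab.dtype)
    if L >= w:
        acc = tab[0][codes[:L - w + 1]]
        for i in range(1, w):
            acc += tab[i][codes[i:L - w + 1 + i]]
        m[:L - w + 1] = acc
    return m


def _comp_prefix(codes: np.ndarray, comp_lo: np.ndarray) -> np.ndarray:
    cp = np.zeros(codes.size + 1, dtype=comp_lo.dtype)
    np.cumsum(comp_lo[codes], out=cp[1:])
    return cp


def viterbi_best_site(window: str | np.ndarray, model: AttcModel,
                      tables: ScoringTables | None = None):
    """Best-scoring site parse anchored at window position 0.

    Maximizes the log-odds score over all admissible (spacer1, loop,
    spacer2) duration triples whose total site length fits both the window
    and the model's site-length bounds.  Returns ``(segment_lengths,
    score)`` or ``None`` if no admissible parse fits.  Ties are broken by
    the lexicographically smallest (spacer1, loop, spacer2).
    """
    if tables is None:
        tables = ScoringTables.from_model(model)
    codes = window if isinstance(window, np.ndarray) else encode_sequence(window, "window")
    L = int(codes.size)
    if L < model.min_site_len:
        return None
    g = tables.grid()
    feasible = g.base_feasible & (g.total <= L)
    if not feasible.any():
        return None
    motif = {name: _motif_positions(codes, tab)
             for name, tab in tables.motif_lo.items()}
    cp = _comp_prefix(codes, tables.comp_lo)
    top = L  # clip target for infeasible entries; cp/motif have L+1 entries
    i_l2 = np.minimum(g.p_l2, top)
    i_loop = np.minimum(g.p_loop, top)
    i_l1 = np.minimum(g.p_l1, top)
    i_s2 = np.minimum(g.p_s2, top)
    i_r1 = np.minimum(g.p_r1, top)
    score = (
        motif["R2"][0]
        + g.ld_sum
        + (cp[i_l2] - cp[LEN_R2])
        + motif["L2"][i_l2]
        + (cp[i_l1] - cp[i_loop])
        + motif["L1"][i_l1]
        + (cp[i_r1] - cp[i_s2])
        + motif["R1"][i_r1]
    )
    score[~feasible] = -np.inf
    flat = int(np.argmax(score))
    best = float(score[flat])
    if not np.isfinite(best):
        return None
    lengths = (LEN_R2, int(g.d1[flat]), LEN_L2, int(g.dl[flat]),
               LEN_L1, int(g.d2[flat]), LEN_R1)
    return lengths, best


def _sweep(codes: np.ndarray, tables: ScoringTables):
    """Per-start generalized Viterbi sweep over one strand (float32).

    Returns ``(best, arg_d1, arg_loop, arg_d2)``.  ``best[s]`` is the best
    score over duration triples for a site starting at ``s``, relaxing only
    the joint site-length bound (per-region supports are enforced), so it
    upper-bounds the constrained optimum; the argmax arrays let the caller
    reconstruct the optimal parse.  Ties take the smallest duration.
    """
    model = tables.model
    L = codes.size
    f32 = np.float32
    neg = f32(-np.inf)
    motif = {name: _motif_positions(codes, tab)
             for name, tab in tables.motif_lo32.items()}
    flat_comp = tables.flat_composition
    cp = None if flat_comp else _comp_prefix(codes, tables.comp_lo32)
    s_lo, s_hi = model.spacer_support
    l_lo, l_hi = model.loop_support

    term = np.empty(L, dtype=f32)
    scratch = np.empty(L, dtype=f32)
    mask = np.empty(L, dtype=bool)

    def shift_into(dst, arr, k, fill):
        n = arr.size - k
        if n <= 0:
            dst[:] = fill
        else:
            n = min(n, L)
            dst[:n] = arr[k:k + n]
            dst[n:] = fill

    def add_cp_diff(dst, hi_off, lo_off):
        # dst += cp[p + hi_off] - cp[p + lo_off]; no-op for flat composition
        if flat_comp:
            return
        cp_end = cp[-1]
        shift_into(scratch, cp, hi_off, cp_end)
        dst += scratch
        shift_into(scratch, cp, lo_off, cp_end)
        dst -= scratch

    def stage_max(best, arg, d, term):
        np.greater(term, best, out=mask)
        np.copyto(best, term, where=mask)
        np.copyto(arg, np.int16(d), where=mask)

    # G(q): L' at q, then spacer2 and R'
    G = np.full(L, neg, dtype=f32)
    arg_d2 = np.zeros(L, dtype=np.int16)
    for d2 in range(s_lo, s_hi + 1):
        shift_into(term, motif["R1"], LEN_L1 + d2, neg)
        term += f32(tables.ld_s2[d2 - s_lo])
        add_cp_diff(term, LEN_L1 + d2, LEN_L1)
        stage_max(G, arg_d2, d2, term)
    G += motif["L1"][:L]

    # H(r): loop starting at r, then G
    H = np.full(L, neg, dtype=f32)
    arg_loop = np.zeros(L, dtype=np.int16)
    for dloop in range(l_lo, l_hi + 1):
        shift_into(term, G, dloop, neg)
        term += f32(tables.ld_loop[dloop - l_lo])
        add_cp_diff(term, dloop, 0)
        stage_max(H, arg_loop, dloop, term)

    # F(p): L'' at p, then H;  best(s): R'' at s, spacer1, then F
    F = motif["L2"][:L]
    shift_into(term, H, LEN_L2, neg)
    F = F + term
    best = np.full(L, neg, dtype=f32)
    arg_d1 = np.zeros(L, dtype=np.int16)
    for d1 in range(s_lo, s_hi + 1):
        shift_into(term, F, LEN_R2 + d1, neg)
        term += f32(tables.ld_s1[d1 - s_lo])
        add_cp_diff(term, LEN_R2 + d1, LEN_R2)
        stage_max(best, arg_d1, d1, term)
    best += motif["R2"][:L]
    return best, arg_d1, arg_loop, arg_d2


def _scores_at(codes: np.ndarray, pos: np.ndarray, tab: np.ndarray) -> np.ndarray:
    """Double-precision motif scores at selected positions (all in range)."""
    acc = tab[0][codes[pos]]
    for i in range(1, tab.shape[0]):
        acc = acc + tab[i][codes[pos + i]]
    return acc


#: gate slack absorbing float32 rounding in the sweep's upper bound
_GATE_EPS = 1e-3


def _strand_hits(codes: np.ndarray, tables: ScoringTables,
                 score_threshold: float):
    """Hits on one scanned strand as (start, site_len, lengths, score).

    Candidates come from the sweep; each optimal parse is reconstructed
    from the argmax chain and re-scored in double precision.  The rare
    starts whose unconstrained optimum violates the site-length bounds
    fall back to exact enumeration.
    """
    model = tables.model
    L = codes.size
    best, arg_d1, arg_loop, arg_d2 = _sweep(codes, tables)
    cand = np.nonzero(best > score_threshold - _GATE_EPS)[0]
    if cand.size == 0:
        return []
    s_lo = model.spacer_support[0]
    l_lo = model.loop_support[0]
    d1 = arg_d1[cand].astype(np.int64)
    p_l2 = np.minimum(cand + LEN_R2 + d1, L - 1)
    dl = arg_loop[np.minimum(p_l2 + LEN_L2, L - 1)].astype(np.int64)
    p_l1c = np.minimum(p_l2 + LEN_L2 + dl, L - 1)
    d2 = arg_d2[p_l1c].astype(np.int64)
    total = MOTIF_TOTAL + d1 + dl + d2
    feasible = ((total >= model.min_site_len) & (total <= model.max_site_len)
                & (cand + total <= L) & (d1 > 0) & (dl > 0) & (d2 > 0))

    out = []
    fi = np.nonzero(feasible)[0]
    if fi.size:
        fc = cand[fi]
        fd1, fdl, fd2 = d1[fi], dl[fi], d2[fi]
        p_l2 = fc + LEN_R2 + fd1
        p_loop = p_l2 + LEN_L2
        p_l1 = p_loop + fdl
        p_s2 = p_l1 + LEN_L1
        p_r1 = p_s2 + fd2
        score = (
            _scores_at(codes, fc, tables.motif_lo["R2"])
            + tables.ld_s1[fd1 - s_lo] + tables.ld_loop[fdl - l_lo]
            + tables.ld_s2[fd2 - s_lo]
            + _scores_at(codes, p_l2, tables.motif_lo["L2"])
            + _scores_at(codes, p_l1, tables.motif_lo["L1"])
            + _scores_at(codes, p_r1, tables.motif_lo["R1"])
        )
        if not tables.flat_composition:
            cp = _comp_prefix(codes, tables.comp_lo)
            score = score + ((cp[p_l2] - cp[fc + LEN_R2])
                             + (cp[p_l1] - cp[p_loop])
                             + (cp[p_r1] - cp[p_s2]))
        keep = score > score_threshold
        for j in np.nonzero(keep)[0]:
            lengths = (LEN_R2, int(fd1[j]), LEN_L2, int(fdl[j]),
                       LEN_L1, int(fd2[j]), LEN_R1)
            out.append((int(fc[j]), int(total[fi[j]]), lengths,
                        float(score[j])))
    for i in np.nonzero(~feasible)[0]:
        s = int(cand[i])
        parsed = viterbi_best_site(codes[s:s + model.max_site_len],
                                   model, tables)
        if parsed is not None and parsed[1] > score_threshold:
            lengths, sc = parsed
            out.append((s, sum(lengths), lengths, float(sc)))
    out.sort(key=lambda t: t[0])
    return out


def _greedy_reduce(hits: list[AttcHit], contig_len: int) -> list[AttcHit]:
    """Keep the best of mutually overlapping hits (same strand assumed).

    Best-first by score; ties broken by leftmost start.  The output is
    pairwise non-overlapping.
    """
    occupied = np.zeros(contig_len, dtype=bool)
    kept: list[AttcHit] = []
    for hit in sorted(hits, key=lambda h: (-h.hmm_score, h.start, h.end)):
        if not occupied[hit.start:hit.end].any():
            occupied[hit.start:hit.end] = True
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def scan_sequence(record, model: AttcModel, score_threshold: float = 0.0,
                  tables: ScoringTables | None = None) -> list[AttcHit]:
    """Scan both strands of a sequence record for candidate attC sites.

    ``record`` may be a Bio.SeqRecord, an (id, sequence) pair, or a plain
    string.  Returns hits with ``hmm_score`` strictly above
    ``score_threshold``, coordinates projected onto the top strand.  Within
    each strand, locally overlapping candidate parses are reduced to the
    best-scoring one; cross-strand overlaps are retained for the structure
    stage to resolve.
    """
    contig_id, seq = _record_parts(record)
    if not seq:
        return []
    if tables is None:
        tables = ScoringTables.from_model(model)
    top = encode_sequence(seq, contig_id)
    L = top.size
    all_hits: list[AttcHit] = []
    for strand, codes in (("+", top), ("-", revcomp_codes(top))):
        if L < model.min_site_len:
            continue
        hits: list[AttcHit] = []
        for s, site_len, lengths, score in _strand_hits(codes, tables,
                                                        score_threshold):
            if strand == "+":
                start, end = s, s + site_len
            else:
                start, end = L - (s + site_len), L - s
            hits.append(AttcHit(contig_id=contig_id, strand=strand,
                                start=start, end=end,
                                segment_lengths=lengths, hmm_score=score))
        all_hits.extend(_greedy_reduce(hits, L))
    all_hits.sort(key=lambda h: (h.start, h.strand))
    return all_hits


def _record_parts(record) -> tuple[str, str]:
    if isinstance(record, str):
        return "seq", record
    if isinstance(record, tuple):
        return record[0], str(record[1])
    # Bio.SeqRecord duck-typing
    return record.id, str(record.seq)
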
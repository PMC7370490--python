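"""Complete-ORF finding on both strands, bacterial genetic code (table 11).

Only *complete* ORFs are reported: from the first permitted start codon
(ATG/GTG/TTG) after an in-frame stop (or the contig edge) to the next
in-frame stop codon, entirely inside the contig.  Genes are never allowed
to run off the contig edges.  Each ORF gets a length-based log-odds score
against the expected open-frame run length under the background
composition; only ORFs with a positive score are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
from Bio.Seq import Seq

from .model import reverse_complement

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_BASE_TO_INT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_INT[ord(_b)] = _i
    _BASE_TO_INT[ord(_b.lower())] = _i


def _codon_value(codon: str) -> int:
    return (_BASE_TO_INT[ord(codon[0])] * 16
            + _BASE_TO_INT[ord(codon[1])] * 4
            + _BASE_TO_INT[ord(codon[2])])


_START_VALUES = frozenset(_codon_value(c) for c in START_CODONS)
_STOP_VALUES = frozenset(_codon_value(c) for c in STOP_CODONS)


@dataclass
class OrfRecord:
    """A complete predicted gene on a contig.

    ``start``/``end`` are 0-based half-open on the top strand and include
    the stop codon; ``nt_seq`` is the coding-strand sequence and ``aa_seq``
    the translation (table 11, initiator as Met, stop excluded).
    """

    contig_id: str
    strand: str
    start: int
    end: int
    frame: int
    orf_score: float
    nt_seq: str
    aa_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _translate(nt_seq: str) -> str:
    aa = str(Seq(nt_seq[:-3]).translate(table=11))
    # initiator codons (ATG/GTG/TTG) all code for fMet in bacteria
    return "M" + aa[1:] if aa else aa


def expected_orf_codons(background_gc: float = 0.5) -> float:
    """Expected open-frame run length (codons) under a 0-order background.

    With per-base composition p, the stop-codon probability per codon is
    p(TAA)+p(TAG)+p(TGA) and the expected run between stops is its inverse
    (64/3 codons for the uniform background).
    """
    at = (1.0 - background_gc) / 2.0
    g = background_gc / 2.0
    p_stop = at * at * at + at * at * g + at * g * at
    return 1.0 / p_stop


def orf_score(n_codons: int, background_gc: float = 0.5) -> float:
    """ln(length in codons / expected open-frame length under background)."""
    return log(n_codons / expected_orf_codons(background_gc))


def _scan_strand(codes: np.ndarray, min_len: int, background_gc: float):
    """Yield (frame, start, end, n_codons) of complete ORFs on one strand."""
    L = codes.size
    for frame in range(3):
        n = (L - frame) // 3
        if n < 2:
            continue
        codons = codes[frame:frame + 3 * n].reshape(n, 3)
        valid = (codons >= 0).all(axis=1)
        vals = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
        is_stop = valid & np.isin(vals, tuple(_STOP_VALUES))
        is_start = valid & np.isin(vals, tuple(_START_VALUES))
        stops = np.nonzero(is_stop)[0]
        starts = np.nonzero(is_start)[0]
        prev_stop = -1
        for stop in stops:
            idx = np.searchsorted(starts, prev_stop + 1)
            if idx < starts.size and starts[idx] < stop:
                first_start = int(starts[idx])
                n_codons = int(stop) - first_start + 1  # includes stop codon
                nt_len = 3 * n_codons
                if nt_len >= min_len:
                    yield (frame, frame + 3 * first_start,
                           frame + 3 * (int(stop) + 1), n_codons)
            prev_stop = int(stop)


def find_orfs(record, min_len: int = 75, background_gc: float = 0.5) -> list[OrfRecord]:
    """All maximal complete ORFs on both strands (six frames).

    ``min_len`` is in nucleotides including the stop codon.  ORFs whose
    length-based score is not positive are dropped.
    """
    from .scan import _record_parts
    contig_id, seq = _record_parts(record)
    seq = seq.upper()
    L = len(seq)
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        sseq = seq if strand == "+" else reverse_complement(seq)
        codes = _BASE_TO_INT[np.frombuffer(sseq.encode("ascii", "replace"),
                                           dtype=np.uint8)]
        for frame, s, e, n_codons in _scan_strand(codes, min_len, background_gc):
            score = orf_score(n_codons, background_gc)
            if score <= 0:
                continue
            nt = sseq[s:e]
            if strand == "+":
                start, end = s, e
            else:
                start, end = L - e, L - s
            out.append(OrfRecord(
                contig_id=contig_id, strand=strand, start=start, end=end,
                frame=frame, orf_score=score, nt_seq=nt, aa_seq=_translate(nt)))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out
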
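"""Non-redundant gene-cassette catalog and its summary statistics.

The unit of the catalog is the (attC nucleotide sequence, ORF nucleotide
sequence) pair: cassettes whose attC *and* ORF sequences are both
identical collapse to one entry.  Diversity is assessed by greedy
centroid clustering of the protein sequences (CD-HIT style): sequences are
visited by decreasing length and join the first established centroid whose
global-alignment identity reaches the cutoff, otherwise they found a new
cluster.  Summary statistics mirror a survey report: ORF length and G/C
medians and standard deviations, plus attC abundance in copies per
million bases scanned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .assembly import Cassette


@dataclass
class CatalogEntry:
    """One deduplicated (attC, ORF) pair with provenance of its first sighting."""

    entry_id: str
    attc_seq: str
    orf_nt: str
    orf_aa: str
    contig_id: str
    orf_start: int
    orf_end: int
    strand: str

    @property
    def length_nt(self) -> int:
        return len(self.orf_nt)

    @property
    def gc(self) -> float:
        s = self.orf_nt.upper()
        if not s:
            return 0.0
        return (s.count("G") + s.count("C")) / len(s)


def deduplicate(cassettes: list[Cassette], sequences: dict[str, str]) -> list[CatalogEntry]:
    """One entry per distinct (attC sequence, ORF sequence) pair.

    ``sequences`` maps contig id to its top-strand sequence, used to
    extract the attC site in scanned-strand orientation.  Cassettes without
    ORFs contribute nothing (they are counted in the scan report instead).
    The first occurrence's provenance is kept; the operation is idempotent.
    """
    seen: dict[tuple[str, str], CatalogEntry] = {}
    for cassette in cassettes:
        attc = cassette.attc
        attc_seq = attc.site_sequence(sequences[attc.contig_id])
        for orf in cassette.orfs:
            key = (attc_seq, orf.nt_seq)
            if key in seen:
                continue
            seen[key] = CatalogEntry(
                entry_id=f"GC{len(seen) + 1:06d}",
                attc_seq=attc_seq, orf_nt=orf.nt_seq, orf_aa=orf.aa_seq,
                contig_id=orf.contig_id, orf_start=orf.start,
                orf_end=orf.end, strand=orf.strand)
    return list(seen.values())


@dataclass
class ClusterResult:
    """Partition of protein ids at one identity cutoff."""

    cutoff: float
    clusters: list[list[str]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    @property
    def max_cluster_size(self) -> int:
        return max((len(c) for c in self.clusters), default=0)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity of the best global alignment: matches / alignment length.

    Alignment length counts matched, mismatched and gapped columns; end
    gaps are penalized, so a short sequence can never be highly identical
    to a much longer one.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def _composition_bound(counts_a: np.ndarray, counts_b: np.ndarray,
                       len_a: int, len_b: int) -> float:
    """Upper bound on identity from residue compositions alone."""
    matches_bound = np.minimum(counts_a, counts_b).sum()
    return matches_bound / max(len_a, len_b)


_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY*X"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}


def _aa_counts(seq: str) -> np.ndarray:
    counts = np.zeros(len(_AA_ORDER))
    for c in seq:
        counts[_AA_INDEX.get(c, len(_AA_ORDER) - 1)] += 1
    return counts


def cluster_by_identity(proteins: list[tuple[str, str]], cutoff: float) -> ClusterResult:
    """Single-pass greedy centroid clustering at an identity cutoff.

    ``proteins`` is a list of (id, amino-acid sequence).  Sequences are
    processed by decreasing length (ties by sequence, then id, for
    determinism); each joins the earliest-founded centroid whose
    global-alignment identity is >= ``cutoff``, else founds a new cluster.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    for pid, seq in proteins:
        if not seq:
            raise ValueError(f"protein {pid!r} has an empty sequence")
    order = sorted(proteins, key=lambda p: (-len(p[1]), p[1], p[0]))
    aligner = _make_aligner()
    centroids: list[tuple[str, np.ndarray, int]] = []  # (seq, counts, cluster idx)
    clusters: list[list[str]] = []
    for pid, seq in order:
        counts = _aa_counts(seq)
        placed = False
        for cseq, ccounts, ci in centroids:
            if _composition_bound(counts, ccounts, len(seq), len(cseq)) < cutoff:
                continue
            if global_identity(seq, cseq, aligner) >= cutoff:
                clusters[ci].append(pid)
                placed = True
                break
        if not placed:
            centroids.append((seq, counts, len(clusters)))
            clusters.append([pid])
    return ClusterResult(cutoff=cutoff, clusters=clusters)


def summarize(entries: list[CatalogEntry], total_bases_scanned: int,
              n_attc: int) -> dict:
    """Catalog summary: length and G/C statistics plus attC abundance.

    Abundance is reported as copies per million bases scanned
    (n_attc * 1e6 / total_bases_scanned).  With an empty catalog the
    medians are reported as NaN and flagged undefined.
    """
    if total_bases_scanned <= 0:
        raise ValueError("total_bases_scanned must be positive")
    lengths = np.array([e.length_nt for e in entries], dtype=float)
    gcs = np.array([e.gc for e in entries], dtype=float)
    empty = lengths.size == 0
    return {
        "n_entries": int(lengths.size),
        "length_median": float(np.median(lengths)) if not empty else float("nan"),
        "length_sd": float(np.std(lengths, ddof=1)) if lengths.size > 1 else float("nan"),
        "gc_median": float(np.median(gcs)) if not empty else float("nan"),
        "gc_sd": float(np.std(gcs, ddof=1)) if gcs.size > 1 else float("nan"),
        "attc_copies_per_mb": n_attc * 1e6 / total_bases_scanned,
        "medians_defined": not empty,
    }
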
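"""Assembly of validated attC sites into cassette arrays and ORF association.

Consecutive attC sites on the same contig and strand that lie within a
bounded distance of each other (4000 nt by default, a conservative upper
limit on cassette gene length) are chained into one array; isolated sites
are discarded as probable false positives, since most integrons carry more
than one cassette.  Predicted ORFs are then associated with the array:
each ORF is assigned to the nearest attC site downstream of it on the
cassette strand, provided it overlaps no attC site by more than 50 nt and,
for the first cassette of an array, ends no more than 500 nt before its
attC site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .orfs import OrfRecord
from .scan import AttcHit


@dataclass
class CassetteArray:
    """Same-strand attC sites within proximity range, one putative integron."""

    contig_id: str
    strand: str
    attc_sites: list[AttcHit]

    @property
    def gaps(self) -> list[int]:
        """Inter-site gaps (end of one site to start of the next), in nt."""
        sites = self.attc_sites
        return [sites[i + 1].start - sites[i].end for i in range(len(sites) - 1)]

    def __len__(self) -> int:
        return len(self.attc_sites)


@dataclass
class Cassette:
    """One gene cassette: an attC site plus its associated upstream ORFs."""

    attc: AttcHit
    orfs: list[OrfRecord] = field(default_factory=list)
    ordinal: int = 1  # 1 = first cassette of its array


def group_arrays(hits: list[AttcHit], max_gap: int = 4000) -> list[CassetteArray]:
    """Single-linkage chaining of resolved hits per (contig, strand).

    Consecutive sites whose edge gap is <= ``max_gap`` join one array;
    arrays with a single site are discarded.  Deterministic and invariant
    to the input order.
    """
    by_group: dict[tuple[str, str], list[AttcHit]] = {}
    for hit in hits:
        by_group.setdefault((hit.contig_id, hit.strand), []).append(hit)
    arrays: list[CassetteArray] = []
    for (contig_id, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: (h.start, h.end))
        chain: list[AttcHit] = []
        for hit in group:
            if chain and hit.start - chain[-1].end > max_gap:
                if len(chain) >= 2:
                    arrays.append(CassetteArray(contig_id, strand, chain))
                chain = []
            chain.append(hit)
        if len(chain) >= 2:
            arrays.append(CassetteArray(contig_id, strand, chain))
    arrays.sort(key=lambda a: (a.contig_id, a.attc_sites[0].start, a.strand))
    return arrays


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _contig_length_hint(orfs: list[OrfRecord], arrays: list[CassetteArray]) -> int:
    ends = [o.end for o in orfs] + [a.attc_sites[-1].end for a in arrays]
    return max(ends) if ends else 0


def associate_orfs(arrays: list[CassetteArray], orfs: list[OrfRecord],
                   max_overlap: int = 50, first_gap: int = 500,
                   contig_lengths: dict[str, int] | None = None) -> list[Cassette]:
    """Assign ORFs to cassettes per the upstream-association rules.

    Working in cassette-strand coordinates (minus-strand arrays are
    mirrored), an ORF joins the nearest attC site downstream of it within
    its array, subject to: same contig and strand; overlap with every attC
    of the array <= ``max_overlap``; for the first cassette, the ORF ends
    at most ``first_gap`` nt before its attC; for later cassettes, the ORF
    lies between the previous attC and its own.  A cassette may hold any
    number of ORFs, including none; no ORF is assigned twice.
    """
    cassettes: list[Cassette] = []
    for array in arrays:
        clen = None
        if contig_lengths is not None:
            clen = contig_lengths.get(array.contig_id)
        if clen is None:
            clen = _contig_length_hint(
                [o for o in orfs if o.contig_id == array.contig_id], [array])

        def fwd(start: int, end: int) -> tuple[int, int]:
            if array.strand == "+":
                return start, end
            return clen - end, clen - start

        attcs = sorted((fwd(h.start, h.end) + (h,) for h in array.attc_sites),
                       key=lambda t: t[0])
        per_ordinal: dict[int, list[OrfRecord]] = {i + 1: [] for i in range(len(attcs))}
        candidates = [o for o in orfs
                      if o.contig_id == array.contig_id and o.strand == array.strand]
        for orf in candidates:
            os_, oe = fwd(orf.start, orf.end)
            # nearest attC downstream: first site starting at/after the ORF
            # end, allowing the permitted overlap
            own = None
            for ordinal, (as_, ae, _) in enumerate(attcs, start=1):
                if as_ >= oe - max_overlap:
                    own = ordinal
                    break
            if own is None:
                continue
            if any(_overlap(os_, oe, as_, ae) > max_overlap for as_, ae, _ in attcs):
                continue
            as_, ae, _ = attcs[own - 1]
            if own == 1:
                if as_ - oe > first_gap:
                    continue
            else:
                prev_start, prev_end, _ = attcs[own - 2]
                # the ORF must lie between the previous attC and its own
                if os_ < prev_end - max_overlap:
                    continue
            per_ordinal[own].append(orf)
        for ordinal, (_, _, hit) in enumerate(attcs, start=1):
            members = sorted(per_ordinal[ordinal], key=lambda o: (o.start, o.end))
            cassettes.append(Cassette(attc=hit, orfs=members, ordinal=ordinal))
    return cassettes
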
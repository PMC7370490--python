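"""GFF3 output for detected and planted features.

Coordinates are 1-based inclusive in GFF3 (the library uses 0-based
half-open internally).  Feature types: ``attC_site`` with the scores and
segment lengths as attributes, and ``CDS`` with the cassette ordinal.
"""

from __future__ import annotations

from .assembly import Cassette, CassetteArray
from .simulate import SimTruth

GFF_HEADER = "##gff-version 3"
SOURCE = "cassettescan"


def _fmt(contig: str, ftype: str, start0: int, end0: int, score, strand: str,
         attrs: dict) -> str:
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    score_s = f"{score:.4f}" if score is not None else "."
    return (f"{contig}\t{SOURCE}\t{ftype}\t{start0 + 1}\t{end0}\t{score_s}"
            f"\t{strand}\t.\t{attr_s}")


def cassettes_to_gff(arrays: list[CassetteArray],
                     cassettes: list[Cassette]) -> str:
    lines = [GFF_HEADER]
    hit_array = {}
    for ai, array in enumerate(arrays, start=1):
        for hit in array.attc_sites:
            hit_array[id(hit)] = ai
    for ci, cassette in enumerate(cassettes, start=1):
        hit = cassette.attc
        ai = hit_array.get(id(hit), 0)
        attc_id = f"attC_{ci:05d}"
        lines.append(_fmt(
            hit.contig_id, "attC_site", hit.start, hit.end, hit.hmm_score,
            hit.strand,
            {"ID": attc_id, "array": ai, "ordinal": cassette.ordinal,
             "hmm_score": f"{hit.hmm_score:.4f}",
             "structure_score": (f"{hit.structure_score:.4f}"
                                 if hit.structure_score is not None else "NA"),
             "segment_lengths": ",".join(map(str, hit.segment_lengths))}))
        for oi, orf in enumerate(cassette.orfs, start=1):
            lines.append(_fmt(
                orf.contig_id, "CDS", orf.start, orf.end, orf.orf_score,
                orf.strand,
                {"ID": f"{attc_id}.orf{oi}", "Parent": attc_id,
                 "cassette_ordinal": cassette.ordinal}))
    return "\n".join(lines) + "\n"


def truth_to_gff(truth: SimTruth) -> str:
    lines = [GFF_HEADER]
    for i, t in enumerate(truth.attcs, start=1):
        lines.append(_fmt(
            t.contig_id, "attC_site", t.start, t.end, None, t.strand,
            {"ID": f"true_attC_{i:05d}", "array": t.array_id,
             "ordinal": t.ordinal,
             "segment_lengths": ",".join(map(str, t.segment_lengths))}))
    for i, t in enumerate(truth.orfs, start=1):
        lines.append(_fmt(
            t.contig_id, "CDS", t.start, t.end, None, t.strand,
            {"ID": f"true_orf_{i:05d}", "array": t.array_id,
             "ordinal": t.ordinal}))
    return "\n".join(lines) + "\n"
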
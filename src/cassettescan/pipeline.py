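"""End-to-end detection pipeline.

Stages, in order: gHMM scan of both strands -> hairpin structure
validation -> cross-strand overlap resolution -> proximity grouping with
singleton removal -> complete-ORF finding -> upstream ORF association ->
catalog deduplication and summary.  ORF finding runs only on contigs that
retained at least one cassette array.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import pandas as pd

from . import catalog as catalog_mod
from .assembly import Cassette, CassetteArray, associate_orfs, group_arrays
from .gff import cassettes_to_gff
from .model import AttcModel, build_default_model
from .orfs import OrfRecord, find_orfs
from .scan import AttcHit, ScoringTables, scan_sequence
from .structure import resolve_overlaps, validate_hits

logger = logging.getLogger("cassettescan")


@dataclass
class ScanConfig:
    """Thresholds of the detection pipeline (defaults as calibrated)."""

    model_path: str | None = None
    score_threshold: float = 0.0
    min_structure: float = 0.75
    max_gap: int = 4000
    max_overlap: int = 50
    first_gap: int = 500
    min_orf_len: int = 75
    output_prefix: str = "cassettescan"
    seed: int = 0

    def check(self) -> None:
        for name in ("min_structure", "max_gap", "max_overlap",
                     "first_gap", "min_orf_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def load_model(self) -> AttcModel:
        if self.model_path:
            return AttcModel.load(self.model_path)
        return build_default_model()


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the run report."""

    hits_raw: list[AttcHit]
    arrays: list[CassetteArray]
    cassettes: list[Cassette]
    orfs: list[OrfRecord]
    entries: list
    report: dict
    sequences: dict = field(default_factory=dict)

    def to_gff(self) -> str:
        return cassettes_to_gff(self.arrays, self.cassettes)

    def cassette_table(self) -> pd.DataFrame:
        rows = []
        for cassette in self.cassettes:
            hit = cassette.attc
            base = {
                "contig": hit.contig_id, "strand": hit.strand,
                "ordinal": cassette.ordinal,
                "attc_start": hit.start, "attc_end": hit.end,
                "hmm_score": hit.hmm_score,
                "structure_score": hit.structure_score,
            }
            if cassette.orfs:
                for orf in cassette.orfs:
                    rows.append({**base, "orf_start": orf.start,
                                 "orf_end": orf.end, "orf_score": orf.orf_score})
            else:
                rows.append({**base, "orf_start": pd.NA, "orf_end": pd.NA,
                             "orf_score": pd.NA})
        columns = ["contig", "strand", "ordinal", "attc_start", "attc_end",
                   "hmm_score", "structure_score", "orf_start", "orf_end",
                   "orf_score"]
        return pd.DataFrame(rows, columns=columns)

    def catalog_tables(self) -> tuple[pd.DataFrame, list, list]:
        """(entry table, nucleotide FASTA records, protein FASTA records)."""
        rows, nt, aa = [], [], []
        for e in self.entries:
            rows.append({
                "entry_id": e.entry_id, "contig": e.contig_id,
                "strand": e.strand, "orf_start": e.orf_start,
                "orf_end": e.orf_end, "length_nt": e.length_nt,
                "gc": e.gc, "attc_seq": e.attc_seq,
            })
            nt.append((e.entry_id, e.orf_nt))
            aa.append((e.entry_id, e.orf_aa))
        columns = ["entry_id", "contig", "strand", "orf_start", "orf_end",
                   "length_nt", "gc", "attc_seq"]
        return pd.DataFrame(rows, columns=columns), nt, aa


def run_pipeline(config: ScanConfig, records: list[tuple[str, str]],
                 model: AttcModel | None = None) -> PipelineResult:
    """Run scan -> validate -> resolve -> group -> ORFs -> associate -> catalog.

    ``records`` are (contig_id, sequence) pairs.  Succeeds with empty
    outputs when nothing is found.
    """
    config.check()
    if model is None:
        model = config.load_model()
    tables = ScoringTables.from_model(model)
    sequences = {rid: seq for rid, seq in records}
    total_bases = sum(len(seq) for seq in sequences.values())

    hits_raw: list[AttcHit] = []
    resolved: list[AttcHit] = []
    for rid, seq in records:
        hits = scan_sequence((rid, seq), model, config.score_threshold, tables)
        hits_raw.extend(hits)
        validated = validate_hits(hits, (rid, seq), config.min_structure)
        resolved.extend(resolve_overlaps(validated))
    logger.info("scan: %d raw hits, %d after structure validation and "
                "overlap resolution", len(hits_raw), len(resolved))

    arrays = group_arrays(resolved, config.max_gap)
    kept_sites = sum(len(a) for a in arrays)
    logger.info("grouping: %d arrays keeping %d attC sites "
                "(singletons removed)", len(arrays), kept_sites)

    contigs_with_arrays = {a.contig_id for a in arrays}
    orfs: list[OrfRecord] = []
    for rid in sorted(contigs_with_arrays):
        orfs.extend(find_orfs((rid, sequences[rid]), min_len=config.min_orf_len))
    cassettes = associate_orfs(
        arrays, orfs, max_overlap=config.max_overlap,
        first_gap=config.first_gap,
        contig_lengths={rid: len(seq) for rid, seq in sequences.items()})
    associated = [o for c in cassettes for o in c.orfs]
    logger.info("association: %d ORFs assigned to %d cassettes",
                len(associated), len(cassettes))

    entries = catalog_mod.deduplicate(cassettes, sequences)
    summary = catalog_mod.summarize(entries, total_bases, kept_sites) \
        if total_bases else {}
    report = {
        "total_bases_scanned": total_bases,
        "n_contigs": len(records),
        "n_raw_hits": len(hits_raw),
        "n_validated_hits": len(resolved),
        "n_arrays": len(arrays),
        "n_attc": kept_sites,
        "n_orfs_associated": len(associated),
        "n_cassettes": len(cassettes),
        "n_catalog_entries": len(entries),
        "attc_copies_per_mb": summary.get("attc_copies_per_mb", 0.0),
        "length_median": summary.get("length_median"),
        "length_sd": summary.get("length_sd"),
        "gc_median": summary.get("gc_median"),
        "gc_sd": summary.get("gc_sd"),
    }
    return PipelineResult(hits_raw=hits_raw, arrays=arrays,
                          cassettes=cassettes, orfs=orfs, entries=entries,
                          report=report, sequences=sequences)
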
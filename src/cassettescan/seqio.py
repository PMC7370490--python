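"""FASTA input/output with strict validation.

Reading goes through Biopython's parser, then sequences are uppercased and
checked against the IUPAC nucleotide alphabet; structural problems
(missing header, empty record) are reported with the offending line
number.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scan import SequenceAlphabetError, encode_sequence


class FastaFormatError(ValueError):
    pass


def _structural_check(path) -> None:
    """Report missing headers / empty records with their line numbers."""
    with open(path) as fh:
        header_line = None
        seen_seq = False
        seen_any = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not seen_seq:
                    raise FastaFormatError(
                        f"{path}:{header_line}: record has an empty sequence")
                if stripped == ">":
                    raise FastaFormatError(
                        f"{path}:{lineno}: record header has no identifier")
                header_line = lineno
                seen_seq = False
                seen_any = True
            else:
                if header_line is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any '>' header")
                seen_seq = True
        if header_line is not None and not seen_seq:
            raise FastaFormatError(
                f"{path}:{header_line}: record has an empty sequence")
        if not seen_any:
            raise FastaFormatError(f"{path}:1: no FASTA records found")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs, in file order.

    Accepts line-wrapped and single-line dialects and IUPAC ambiguity
    codes; malformed records and non-nucleotide characters raise with a
    location.
    """
    _structural_check(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        encode_sequence(seq, rec.id)  # alphabet check, names the position
        records.append((rec.id, seq))
    return records


def write_fasta(path, records: list[tuple[str, str]], width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="")
                   for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
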
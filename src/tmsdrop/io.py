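"""FASTA input/output for invader and pool strands (via Biopython)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .pool_thermo import DNAStrand

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[DNAStrand]:
    """Read DNA strands from a FASTA file (sequences upper-cased)."""
    strands = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            strands.append(DNAStrand(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not strands:
        raise ParseError(f"{path}: no FASTA records found")
    return strands


def write_fasta(strands: Sequence[DNAStrand], path: str | Path) -> None:
    """Write strands to FASTA."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in strands
    ]
    SeqIO.write(records, str(path), "fasta")
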
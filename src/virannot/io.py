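"""Thin FASTA/FASTQ IO wrappers (Biopython-backed).

Headers are kept verbatim (the seqtable packs metadata into them), so
records travel as plain ``(header, sequence)`` string pairs.
"""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write reads with a constant (synthetic) Sanger quality string."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f"@{header}\n{seq}\n+\n{quality_char * len(seq)}\n")
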
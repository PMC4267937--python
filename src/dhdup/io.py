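"""FASTA/FASTQ input and output plus small tabular writers.

FASTQ parsing goes through Biopython's fast iterator; qualities are
decoded from Phred+33 by default, with Phred+64 available for legacy
instrument output.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .qc import Read

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
]


def read_fastq(path: str | os.PathLike, phred_offset: int = 33) -> Iterator[Read]:
    """Stream reads from a FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            quals -= phred_offset
            if quals.size and quals.min() < 0:
                raise ValueError(
                    f"negative quality in {title!r}: wrong Phred offset {phred_offset}?"
                )
            yield Read(title.split()[0], seq.upper(), quals)


def write_fastq(reads: Iterable[Read], path: str | os.PathLike, phred_offset: int = 33) -> int:
    """Write reads as FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            qual = (np.asarray(read.quals, dtype=np.int16) + phred_offset).astype(np.uint8)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual.tobytes().decode('ascii')}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Stream ``(id, sequence)`` pairs from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 60) -> int:
    """Write ``(id, sequence)`` pairs as wrapped FASTA; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n
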
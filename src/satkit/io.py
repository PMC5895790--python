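"""FASTA / FASTQ / TSV plumbing.

Parsing goes through Biopython; writing uses the dominant dialects
(FASTA wrapped at 60 columns, 4-line FASTQ with Phred+33 qualities).
Reads are carried as lightweight ``ReadRecord`` tuples so that pools of
10^5 reads stay cheap.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

FASTA_WIDTH = 60
PHRED_OFFSET = 33


class ReadRecord(NamedTuple):
    id: str
    seq: str
    qual: str  # Phred+33 encoded, same length as seq


class MalformedRecordError(ValueError):
    """A sequence record violates basic structural constraints."""


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise MalformedRecordError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | os.PathLike, seqs: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Iterate a FASTQ file as ``ReadRecord`` items (Phred+33 assumed)."""
    with open(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual):
                raise MalformedRecordError(
                    f"record {i} ({title.split()[0]}): sequence and quality lengths differ"
                )
            yield ReadRecord(title.split()[0], seq.upper(), qual)


def write_fastq(path: str | os.PathLike, reads: Iterable[ReadRecord]) -> int:
    """Write reads as 4-line FASTQ; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def phred_scores(qual: str, offset: int = PHRED_OFFSET) -> list[int]:
    """Decode a quality string to integer Phred scores."""
    return [ord(c) - offset for c in qual]
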
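"""Read trimming and quality filtering ahead of assignment.

The pipeline mirrors the preprocessing used for centromere ChIP-seq of
single-end 101-nt Illumina reads: drop the first base, truncate to 100 nt,
and keep a read only if at least 95 of its positions reach Phred quality 10.
Reads left shorter than the trim target are discarded (the uniform read
length keeps downstream proportion arithmetic exact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import MalformedRecordError, PHRED_OFFSET, ReadRecord

__all__ = ["QCParams", "QCSummary", "trim_read", "quality_filter", "process_reads", "process_fastq"]


@dataclass(frozen=True)
class QCParams:
    trim_to: int = 100
    drop_leading: int = 1
    min_q: int = 10
    min_bases_at_q: int = 95
    #: whether a base must be strictly above min_q to count; the conventional
    #: reading of a quality "cutoff" is >=, kept configurable because the
    #: boundary behaviour is underdetermined.
    strict: bool = False
    phred_offset: int = PHRED_OFFSET

    def __post_init__(self) -> None:
        if min(self.trim_to, self.drop_leading, self.min_q, self.min_bases_at_q) < 0:
            raise ValueError("QC parameters must be non-negative")
        if self.trim_to < self.min_bases_at_q:
            raise ValueError("trim_to must be >= min_bases_at_q")


@dataclass
class QCSummary:
    reads_in: int = 0
    discarded_short: int = 0
    failed_quality: int = 0
    reads_out: int = 0

    def check(self) -> None:
        assert self.reads_in == self.reads_out + self.discarded_short + self.failed_quality


def trim_read(read: ReadRecord, params: QCParams = QCParams()) -> ReadRecord | None:
    """Drop leading bases and truncate; ``None`` means the read is discarded
    (shorter than the trim target after trimming)."""
    if len(read.seq) != len(read.qual):
        raise MalformedRecordError(
            f"read {read.id}: sequence and quality lengths differ"
        )
    seq = read.seq[params.drop_leading : params.drop_leading + params.trim_to]
    qual = read.qual[params.drop_leading : params.drop_leading + params.trim_to]
    if len(seq) < params.trim_to:
        return None
    return ReadRecord(read.id, seq, qual)


def quality_filter(read: ReadRecord, params: QCParams = QCParams()) -> bool:
    """True iff enough positions reach the Phred cutoff."""
    thresh = params.min_q + params.phred_offset
    if params.strict:
        n_ok = sum(1 for c in read.qual if ord(c) > thresh)
    else:
        n_ok = sum(1 for c in read.qual if ord(c) >= thresh)
    return n_ok >= params.min_bases_at_q


def process_reads(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCSummary]:
    """Trim + filter a pool; returns surviving reads and conserved counters."""
    summary = QCSummary()
    out: list[ReadRecord] = []
    for read in reads:
        summary.reads_in += 1
        trimmed = trim_read(read, params)
        if trimmed is None:
            summary.discarded_short += 1
            continue
        if not quality_filter(trimmed, params):
            summary.failed_quality += 1
            continue
        out.append(trimmed)
    summary.reads_out = len(out)
    summary.check()
    return out, summary


def process_fastq(
    in_path: str, out_path: str, params: QCParams = QCParams()
) -> QCSummary:
    """File-to-file QC: FASTQ in, FASTQ out, counter summary returned."""
    from .io import read_fastq, write_fastq

    reads, summary = process_reads(read_fastq(in_path), params)
    write_fastq(out_path, reads)
    return summary
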
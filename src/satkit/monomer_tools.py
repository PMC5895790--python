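"""Computational validation of tandem organization.

Reconstructed satellite consensus monomers are validated without wet-lab
work by four complementary checks:

* period estimation by shifted self-identity (the lag at which a sequence
  matches itself) recovers the monomer length of a tandem array;
* dot-plot style self-comparison detects internal subrepeats that would
  explain a long monomer as a higher-order repeat;
* outward-facing primer design plus in-silico PCR: primers that point away
  from each other inside one monomer can only amplify across the junction
  between adjacent tandem copies, so an n-copy head-to-tail array yields
  exactly n-1 products of equal length and a lone monomer yields none;
* global percent identity scores cloned amplicons against the predicted
  consensus.

Coordinates are 0-based half-open; the junction product length is
(monomer_length - forward.start) + reverse.end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._seq import encode, revcomp
from .alignment import AlignParams

__all__ = [
    "PeriodEstimate",
    "PrimerPair",
    "NoValidPrimerError",
    "estimate_period",
    "detect_subrepeats",
    "design_outward_primers",
    "in_silico_pcr",
    "percent_identity",
    "wallace_tm",
]


@dataclass(frozen=True)
class PeriodEstimate:
    period: int
    confidence: float  # fraction of positions matching at lag = period


class NoValidPrimerError(ValueError):
    """No primer window satisfies even the relaxed constraints."""


# ---------------------------------------------------------------------------
# periodicity


def _match_fraction(codes: np.ndarray, lag: int) -> float:
    a, b = codes[:-lag], codes[lag:]
    ok = (a == b) & (a < 4)
    return float(ok.mean())


def estimate_period(
    array_seq: str, min_period: int = 1, max_period: int | None = None,
    min_confidence: float = 0.8,
) -> PeriodEstimate | None:
    """Smallest lag in [min_period, max_period] whose self-match fraction
    exceeds ``min_confidence`` and is a local maximum; None if no lag
    qualifies. Reports the fundamental period of a tandem array, never a
    multiple of it (smaller qualifying lags win)."""
    L = len(array_seq)
    if max_period is None:
        max_period = L // 2
    if min_period < 1 or L < 2 * min_period or max_period < min_period:
        raise ValueError("infeasible period search window")
    max_period = min(max_period, L // 2)
    codes = encode(array_seq)
    fracs = np.array(
        [_match_fraction(codes, lag) for lag in range(max(1, min_period - 1), max_period + 2)]
    )
    lags = np.arange(max(1, min_period - 1), max_period + 2)
    for i, lag in enumerate(lags):
        if lag < min_period or lag > max_period:
            continue
        f = fracs[i]
        left = fracs[i - 1] if i > 0 else -1.0
        right = fracs[i + 1] if i + 1 < fracs.size else -1.0
        if f > min_confidence and f >= left and f >= right:
            return PeriodEstimate(int(lag), float(f))
    return None


def detect_subrepeats(
    monomer: str, min_len: int = 20
) -> list[tuple[int, tuple[int, int]]]:
    """Internal periodicities from the self-comparison (dot-plot) matrix.

    Reports off-main-diagonal runs of exact identity of length >= min_len
    at lag < monomer length, as (period, span) with span covering the
    whole repeated region. An empty list means no internal subrepeats.
    """
    L = len(monomer)
    if L < 2 * min_len:
        raise ValueError("monomer shorter than twice min_len")
    codes = encode(monomer)
    out: list[tuple[int, tuple[int, int]]] = []
    for lag in range(1, L - min_len + 1):
        eq = (codes[:-lag] == codes[lag:]) & (codes[:-lag] < 4)
        # run-length scan over the boolean identity diagonal
        padded = np.r_[False, eq, False].astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                out.append((lag, (int(s), int(e + lag))))
    return out


# ---------------------------------------------------------------------------
# primers and in-silico PCR


@dataclass(frozen=True)
class PrimerPair:
    """Outward-facing primer pair within one monomer.

    ``forward`` sits toward the 3' end of the monomer and reads toward
    increasing coordinates (off the end of the copy); ``reverse`` sits
    toward the 5' end and reads toward decreasing coordinates. Hence
    reverse.end <= forward.start and amplification requires an adjacent
    tandem copy.
    """

    forward: tuple[int, int]  # plus-strand span; primer = monomer[start:end]
    reverse: tuple[int, int]  # plus-strand span; primer = revcomp(monomer[start:end])
    forward_seq: str
    reverse_seq: str
    warnings: tuple[str, ...] = field(default=())

    @property
    def forward_gc(self) -> float:
        return _gc(self.forward_seq)

    @property
    def reverse_gc(self) -> float:
        return _gc(self.reverse_seq)

    @property
    def forward_tm(self) -> float:
        return wallace_tm(self.forward_seq)

    @property
    def reverse_tm(self) -> float:
        return wallace_tm(self.reverse_seq)


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def wallace_tm(seq: str) -> float:
    """Wallace rule-of-thumb melting temperature: 2(A+T) + 4(G+C)."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def design_outward_primers(
    monomer: str,
    min_len: int = 18,
    max_len: int = 25,
    gc_range: tuple[float, float] = (0.40, 0.60),
    relaxed_gc_min: float = 0.30,
) -> PrimerPair:
    """Pick an outward-facing pair: forward as close to the monomer 3' end
    as possible, reverse as close to the 5' start, GC 40-60 % where the
    (often AT-rich) input allows, relaxed to >= 30 % with a warning."""
    L = len(monomer)
    if L < 2 * max_len + 1:
        raise NoValidPrimerError(
            f"monomer of {L} bp cannot hold two non-overlapping {max_len}-bp primers"
        )

    def _candidates(region_is_forward: bool, gc_lo: float, gc_hi: float):
        # forward: windows ordered right-to-left in the right half;
        # reverse: windows ordered left-to-right in the left half.
        half = L // 2
        for length in range(min_len, max_len + 1):
            if region_is_forward:
                starts = range(L - length, half - 1, -1)
            else:
                starts = range(0, half - length + 1)
            for s in starts:
                window = monomer[s : s + length]
                if "N" in window:
                    continue
                if gc_lo <= _gc(window) <= gc_hi:
                    yield s, s + length, window
        return

    warn: tuple[str, ...] = ()
    for gc_lo, gc_hi in ((gc_range[0], gc_range[1]), (relaxed_gc_min, 1.0)):
        fwd = next(iter(_candidates(True, gc_lo, gc_hi)), None)
        rev = next(iter(_candidates(False, gc_lo, gc_hi)), None)
        if fwd and rev and rev[1] <= fwd[0]:
            if gc_lo != gc_range[0]:
                warn = (
                    f"GC constraint relaxed to >= {relaxed_gc_min:.0%} on AT-rich input",
                )
                warnings.warn(warn[0])
            f_s, f_e, f_seq = fwd
            r_s, r_e, r_seq = rev
            return PrimerPair(
                forward=(f_s, f_e),
                reverse=(r_s, r_e),
                forward_seq=f_seq,
                reverse_seq=revcomp(r_seq),
                warnings=warn,
            )
    raise NoValidPrimerError("no primer window satisfies the relaxed constraints")


def _occurrences(template: str, motif: str) -> list[int]:
    out, i = [], template.find(motif)
    while i != -1:
        out.append(i)
        i = template.find(motif, i + 1)
    return out


def in_silico_pcr(
    template: str, pair: PrimerPair, max_product: int = 5000
) -> list[int]:
    """Exact-match PCR simulation on both strands.

    A product arises from a primer site priming rightward on the plus
    strand and the *next* downstream site of the other primer priming
    leftward, within ``max_product``. On an n-copy head-to-tail tandem
    array an outward pair therefore yields n-1 equal junction products and
    a single monomer yields none.
    """
    if min(len(pair.forward_seq), len(pair.reverse_seq)) < 15:
        raise ValueError("primers must be at least 15 bp")
    products: list[int] = []
    combos = [
        (pair.forward_seq, pair.reverse_seq),
        (pair.reverse_seq, pair.forward_seq),  # roles swapped = minus strand
    ]
    for right_primer, left_primer in combos:
        fwd_sites = _occurrences(template, right_primer)
        rev_sites = _occurrences(template, revcomp(left_primer))
        rev_ends = sorted(s + len(left_primer) for s in rev_sites)
        for f in fwd_sites:
            downstream = [e for s, e in zip(sorted(rev_sites), rev_ends) if s >= f + len(right_primer)]
            if downstream:
                length = downstream[0] - f
                if length <= max_product:
                    products.append(length)
    return sorted(products)


# ---------------------------------------------------------------------------
# clone-vs-consensus identity


def percent_identity(
    a: str, b: str, params: AlignParams = AlignParams()
) -> float:
    """Global alignment identity (%), end gaps free, using the same
    match/mismatch/affine-gap scores as read assignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.end_gap_score = 0.0  # free end gaps (semi-global identity)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length * 100.0
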
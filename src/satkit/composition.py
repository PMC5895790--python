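"""Sequence-composition indices for satellite monomers and read pools.

Three kinds of statistics are computed:

* AT fraction (N bases excluded).
* Strand-asymmetry indices: for each complementary pair (A vs T, C vs G)
  and for purines vs pyrimidines, the counts on the given strand are
  compared and reported as ``max(x/y, y/x)`` -- always >= 1, with an
  infinity sentinel when one member is absent. Simple-sequence satellites
  (e.g. degenerate (GTT)n expansions) show strong asymmetry.
* Di- and tri-nucleotide relative abundances (the Karlin-school genomic
  signature). Counts are taken circularly -- a satellite monomer is an
  arbitrary rotation of its repeating unit, and circular counts are
  rotation invariant -- and strand-symmetrized (sequence plus reverse
  complement), so these statistics are strand neutral by construction; the
  asymmetry indices above carry the strand signal instead.

  rho*(XY)  = f*(XY) / (f*(X) f*(Y))
  gamma*(XYZ) = f*(XYZ) f*(X) f*(Y) f*(Z) / (f*(XY) f*(YZ) f*(X.Z))

  where f* are symmetrized frequencies and f*(X.Z) is the one-gapped
  dinucleotide frequency (X and Z separated by exactly one base). Both
  statistics equal 1 in expectation on an iid sequence; values for k-mers
  absent from the data are reported as 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, encode, revcomp
from .alignment import AlignParams, local_align_score
from .io import ReadRecord

__all__ = [
    "CompositionProfile",
    "at_content",
    "strand_asymmetry",
    "dinucleotide_rho",
    "trinucleotide_gamma",
    "composition_profile",
    "pool_composition",
]

DINUCLEOTIDES = ["".join(p) for p in itertools.product(BASES, repeat=2)]
TRINUCLEOTIDES = ["".join(p) for p in itertools.product(BASES, repeat=3)]


@dataclass
class CompositionProfile:
    at_fraction: float
    max_at: float
    max_cg: float
    max_pupy: float
    rho: dict[str, float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# counting


@dataclass
class _Counts:
    """Circular k-mer counts of a (set of) sequence(s), given strand."""

    mono: np.ndarray  # (4,)
    di: np.ndarray  # (16,) index 4*x + y
    tri: np.ndarray  # (64,) index 16*x + 4*y + z
    gap: np.ndarray  # (16,) X.Z with one intervening base

    @classmethod
    def zeros(cls) -> "_Counts":
        return cls(np.zeros(4), np.zeros(16), np.zeros(64), np.zeros(16))

    def add(self, other: "_Counts") -> None:
        for name in ("mono", "di", "tri", "gap"):
            getattr(self, name).__iadd__(getattr(other, name))


def _count_circular(seq: str) -> _Counts:
    codes = encode(seq)
    a = codes
    b = np.roll(codes, -1)
    c = np.roll(codes, -2)
    out = _Counts.zeros()
    v = a < 4
    out.mono += np.bincount(a[v], minlength=4)[:4]
    if codes.size >= 2:
        v2 = (a < 4) & (b < 4)
        out.di += np.bincount((a * 4 + b)[v2], minlength=16)[:16]
    if codes.size >= 3:
        v3 = (a < 4) & (b < 4) & (c < 4)
        out.tri += np.bincount((a * 16 + b * 4 + c)[v3], minlength=64)[:64]
        vg = (a < 4) & (c < 4)
        out.gap += np.bincount((a * 4 + c)[vg], minlength=16)[:16]
    return out


def _freq(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return counts / total if total > 0 else counts


def _symmetrized(seqs: list[str]) -> _Counts:
    out = _Counts.zeros()
    for s in seqs:
        out.add(_count_circular(s))
        out.add(_count_circular(revcomp(s)))
    return out


# ---------------------------------------------------------------------------
# per-sequence statistics


def at_content(seq: str) -> float:
    """(A + T) / (A + C + G + T); N excluded from both sides."""
    codes = encode(seq)
    counts = np.bincount(codes[codes < 4], minlength=4)[:4]
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return float((counts[0] + counts[3]) / total)


def _max_ratio(x: float, y: float) -> float:
    if x == 0 and y == 0:
        return 1.0
    if x == 0 or y == 0:
        return float("inf")
    return max(x / y, y / x)


def strand_asymmetry(seq: str) -> tuple[float, float, float]:
    """(max A/T, max C/G, max Pu/Py) from given-strand counts."""
    codes = encode(seq)
    counts = np.bincount(codes[codes < 4], minlength=4)[:4]
    if counts.sum() == 0:
        raise ValueError("sequence has no unambiguous bases")
    a, c, g, t = (float(v) for v in counts)
    return _max_ratio(a, t), _max_ratio(c, g), _max_ratio(a + g, c + t)


def _rho_from(counts: _Counts) -> dict[str, float]:
    f1, f2 = _freq(counts.mono), _freq(counts.di)
    out = {}
    for i, mer in enumerate(DINUCLEOTIDES):
        x, y = i // 4, i % 4
        denom = f1[x] * f1[y]
        out[mer] = float(f2[i] / denom) if f2[i] > 0 else 0.0
    return out


def _gamma_from(counts: _Counts) -> dict[str, float]:
    f1, f2, f3, fg = (
        _freq(counts.mono),
        _freq(counts.di),
        _freq(counts.tri),
        _freq(counts.gap),
    )
    out = {}
    for i, mer in enumerate(TRINUCLEOTIDES):
        x, y, z = i // 16, (i // 4) % 4, i % 4
        if f3[i] == 0:
            out[mer] = 0.0
            continue
        denom = f2[x * 4 + y] * f2[y * 4 + z] * fg[x * 4 + z]
        out[mer] = float(f3[i] * f1[x] * f1[y] * f1[z] / denom)
    return out


def dinucleotide_rho(seq: str) -> dict[str, float]:
    """Symmetrized circular dinucleotide relative abundances rho* (16 values)."""
    if len(seq) < 2:
        raise ValueError("need at least 2 bases")
    return _rho_from(_symmetrized([seq]))


def trinucleotide_gamma(seq: str) -> dict[str, float]:
    """Symmetrized circular trinucleotide relative abundances gamma* (64 values)."""
    if len(seq) < 3:
        raise ValueError("need at least 3 bases")
    return _gamma_from(_symmetrized([seq]))


def composition_profile(seq: str) -> CompositionProfile:
    """Full profile of one sequence (consensus monomer entry point)."""
    max_at, max_cg, max_pupy = strand_asymmetry(seq)
    return CompositionProfile(
        at_fraction=at_content(seq),
        max_at=max_at,
        max_cg=max_cg,
        max_pupy=max_pupy,
        rho=dinucleotide_rho(seq) if len(seq) >= 2 else {},
        gamma=trinucleotide_gamma(seq) if len(seq) >= 3 else {},
    )


# ---------------------------------------------------------------------------
# read-pool statistics


def _orient_to_reference(
    seq: str, reference: str, params: AlignParams
) -> str:
    """Return the read on whichever strand scores better against the
    reference (ties keep the forward strand)."""
    rc = revcomp(seq)
    if local_align_score(rc, reference, params) > local_align_score(seq, reference, params):
        return rc
    return seq


def pool_composition(
    reads: list[ReadRecord] | list[str],
    orientation_reference: str,
    params: AlignParams = AlignParams(),
) -> CompositionProfile:
    """Profile of an unassembled read pool, the way satellite composition is
    estimated without a full-length consensus: orient every read to the
    reference strand, pool the circular counts, then apply the
    per-sequence formulas to the pooled counts."""
    seqs = [r.seq if isinstance(r, ReadRecord) else r for r in reads]
    if not seqs:
        raise ValueError("read pool is empty")
    oriented = [_orient_to_reference(s, orientation_reference, params) for s in seqs]

    given = _Counts.zeros()
    for s in oriented:
        given.add(_count_circular(s))
    sym = _Counts.zeros()
    for s in oriented:
        sym.add(_count_circular(s))
        sym.add(_count_circular(revcomp(s)))

    mono = given.mono
    total = mono.sum()
    if total == 0:
        raise ValueError("pool has no unambiguous bases")
    a, c, g, t = (float(v) for v in mono)
    return CompositionProfile(
        at_fraction=float((mono[0] + mono[3]) / total),
        max_at=_max_ratio(a, t),
        max_cg=_max_ratio(c, g),
        max_pupy=_max_ratio(a + g, c + t),
        rho=_rho_from(sym),
        gamma=_gamma_from(sym),
    )
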
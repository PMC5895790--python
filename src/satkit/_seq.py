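"""Low-level sequence helpers shared across the package.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, ambiguity codes)
maps to 4 and never matches during alignment or k-mer hashing.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte value -> 2-bit code (255 = invalid placeholder, remapped to 4 below)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N -> N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_many(seqs: list[str], length: int) -> np.ndarray:
    """Encode equal-length sequences into an (n, length) uint8 matrix."""
    if not seqs:
        return np.empty((0, length), dtype=np.uint8)
    buf = "".join(seqs).encode("ascii")
    arr = _ENCODE[np.frombuffer(buf, dtype=np.uint8)]
    return arr.reshape(len(seqs), length)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 decodes to N)."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on encoded arrays (works on the last axis)."""
    out = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)
    return out[..., ::-1]
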
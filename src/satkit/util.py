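"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed
    genome-size tables), unlike banker's rounding of built-in round()."""
    factor = 10**ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
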
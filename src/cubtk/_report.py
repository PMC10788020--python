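"""Presentation-layer helpers: half-up rounding and table formatting.

All computation elsewhere is full precision; these helpers apply the
conventional report precision (2 decimals for percentages and ENC, 4 for
regression slope and r) at write time only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import math


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.515 -> 0.52 at 2 digits), NaN passed through."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
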
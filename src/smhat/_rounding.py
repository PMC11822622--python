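"""Round-half-up helpers.

Healthiness scores and money are reported round-half-up (0.25 -> 0.3,
36.5p -> 37p), not banker's rounding, so ``round()`` is not used for any
reported figure.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value: float | int | Fraction, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimal places, ties away from zero."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up_int(value: float | Fraction) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(round_half_up(value, 0))
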
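"""Exact currency arithmetic.

All internal cost arithmetic is carried out on :class:`decimal.Decimal`
values in Australian dollars (2021-22 price year), exact to the cent.
Display rounding — whole dollars, whole percents — happens once, at the
reporting edge, using half-up rounding throughout.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

CENT = Decimal("0.01")


def aud(value) -> Decimal:
    """Coerce a number to a Decimal amount quantised to the cent."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    elif isinstance(value, Decimal):
        d = value
    else:
        d = Decimal(str(value))
    return d.quantize(CENT, rounding=ROUND_HALF_UP)


def as_decimal(value) -> Decimal:
    """Exact Decimal coercion without cent quantisation (for intermediates)."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, Fraction):
        return Decimal(value.numerator) / Decimal(value.denominator)
    return Decimal(str(value))


def round_half_up(value) -> int:
    """Round to the nearest integer, ties away from zero upward.

    Accepts int, float, Decimal or Fraction; Fractions are rounded
    exactly (floor(x + 1/2)), which matters for ties such as 164.5.
    """
    if isinstance(value, int):
        return value
    if isinstance(value, Fraction):
        num, den = (value + Fraction(1, 2)).numerator, (value + Fraction(1, 2)).denominator
        return num // den
    d = value if isinstance(value, Decimal) else Decimal(str(value))
    return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def whole_dollars(amount: Decimal) -> int:
    """Display rounding: cents-exact amount to whole dollars, half-up."""
    return round_half_up(as_decimal(amount))
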
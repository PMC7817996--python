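"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-away-from-zero.

    Report-time rounding convention for all printed rates: exact decimal
    division followed by quantization, so 181/552 -> 32.79 and 163/300 ->
    54.33 regardless of binary floating-point representation.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round a float half-away-from-zero (the tabulation convention)."""
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))
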
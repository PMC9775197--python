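"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round1(x: float) -> float:
    """Round to one decimal place, half away from zero.

    Reported percentages use this convention throughout the package so that
    e.g. 96.875 -> 96.9 regardless of binary float representation.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float) -> float:
    """Percentage share, rounded to one decimal (half-up).

    Returns 0.0 for an empty denominator; callers that need to distinguish
    the undefined case must check the denominator themselves.
    """
    if denominator == 0:
        return 0.0
    return round1(100.0 * numerator / denominator)
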
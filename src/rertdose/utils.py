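"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for doses/radii).

    Python's built-in ``round`` uses banker's rounding; clinical tables
    conventionally round 0.5 up, so 33.45 -> 33.5 and 2.05 -> 2.1.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def days_to_months(days: float) -> float:
    """Convert a duration in days to months at 30 days/month, 1 decimal."""
    return round_half_up(days / 30.0, 1)
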
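"""Rounding rules for reported endpoints.

Endpoints are reported as percentages with mixed precision: values of 10%
or more round half-away-from-zero to the nearest integer; values below 10%
keep one decimal place.  Raw trajectories always stay at full precision —
these rules apply only to human-facing summaries.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away", "reported_percent", "format_percent"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reported_percent(p: float) -> float:
    """A probability as a reported percentage under the mixed-precision rule."""
    pct = p * 100.0
    if pct >= 10.0:
        return round_half_away(pct, 0)
    return round_half_away(pct, 1)


def format_percent(p: float) -> str:
    """String form: integer above 10%, one decimal below ('25%', '2.0%')."""
    pct = reported_percent(p)
    if p * 100.0 >= 10.0:
        return f"{pct:.0f}%"
    return f"{pct:.1f}%"
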
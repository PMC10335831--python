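"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at .5 (the convention of printed
    percentage tables: 70.69 -> 71, 4.17 -> 4, 13.5 -> 14)."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v


def percent(count: int, total: int, ndigits: int = 0) -> float:
    """count/total as a percentage, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round_half_up(100.0 * count / total, ndigits)
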
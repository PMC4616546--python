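"""Percentage formatting shared across modules.

Percentages are displayed with half-up rounding (0.05 rounds to 0.1),
the convention of the clinical literature; exact ratios are retained
internally everywhere.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, decimals: int = 1) -> float:
    """100 * count / total, half-up rounded for display."""
    if total <= 0:
        raise ValueError("percentage undefined: total must be positive")
    return round_half_up(100.0 * count / total, decimals)
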
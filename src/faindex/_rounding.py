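"""Rounding conventions used for all printed percentages.

Tables round half away from zero to one decimal (so 9.45 -> 9.5), which
differs from Python's banker's rounding.
"""

from __future__ import annotations

import math


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero to ``decimals`` places."""
    if math.isnan(x):
        return x
    factor = 10.0**decimals
    scaled = x * factor
    # nudge by one ulp so values like 2.675*10 = 26.749999... still round up
    return math.copysign(math.floor(abs(scaled) + 0.5 + 1e-9), scaled) / factor


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` with table rounding.

    A zero denominator yields NaN (reported as NA in tables).
    """
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, decimals)
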
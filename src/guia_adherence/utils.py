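"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how survey reports print percentages
    (numpy/python banker's rounding would turn 0.25 into 0.2)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(x: float, ndigits: int = 1) -> float:
    """Proportion -> percentage, half-up rounded for report output."""
    return round_half_up(100.0 * x, ndigits)
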
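"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero-ward (half-up), unlike banker's rounding.

    Printed percentages and count estimates in this package are frozen to
    half-up so that e.g. 0.25 -> 0.3 at one decimal and 2.5 -> 3 at zero.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
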
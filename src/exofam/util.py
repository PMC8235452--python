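"""Small shared numerics for reporting."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def pct_half_up(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """100 * numerator / denominator rounded half-up to ``ndigits`` decimals.

    Report tables round half-up at the printed precision (banker's rounding
    would turn e.g. 2.5% into 2%), and the ratio is formed in decimal
    arithmetic so the rounding decision is made on the exact quotient of the
    integer counts, not on a float approximation.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    q = Decimal(1).scaleb(-ndigits)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)
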
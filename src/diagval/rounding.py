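"""Half-up decimal rounding, centralized.

All report-facing rounding goes through this single function so the whole
package shares one convention: round-half-up on the printed scale (the
convention under which 73/106 = 68.867...% prints as 68.9).  Python's
built-in round() is banker's rounding and would print 68.8 for some inputs.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places, ties away from zero toward +inf.

    Uses exact decimal arithmetic on ``repr(x)`` so that values which are
    exactly representable in decimal (the common case for percentages built
    from integer counts) round the way they would by hand.
    """
    if decimals < 0:
        raise ValueError("decimals must be non-negative")
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
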
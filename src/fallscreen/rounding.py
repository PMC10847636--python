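"""Half-up decimal rounding for the reporting layer.

Python's builtin ``round`` is banker's rounding; printed clinical tables
round half away from zero, so 0.425 -> 0.43 and 57.15 -> 57.2.  All metric
arithmetic stays unrounded; rounding is applied only when values are
reported.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
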
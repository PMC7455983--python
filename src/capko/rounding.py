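"""Half-up decimal rounding for display values.

Composition tables round half away from zero (2.15% -> 2.2%, 6.105 ->
6.11); Python's built-in ``round`` is banker's rounding and would give
2.1, so display rounding goes through :mod:`decimal` instead.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
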
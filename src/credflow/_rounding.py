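"""Half-up rounding helpers matching the reporting conventions of the tables.

Python's builtin ``round`` is banker's rounding; published tables in this
field almost universally use half-up, so every printed percentage goes
through :func:`round_half_up` or :func:`round_sig_half_up`.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero."""
    x = float(x)
    if math.isnan(x) or math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig_half_up(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures, ties away from zero."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    x = float(x)
    if x == 0 or math.isnan(x) or math.isinf(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)
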
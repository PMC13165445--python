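"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` with ties away from zero, as tabulated reports do.

    Python's builtin ``round`` uses banker's rounding; published tables
    virtually always round 0.5 up, so reported percentages and genome
    sizes go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
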
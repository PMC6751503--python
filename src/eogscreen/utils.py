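"""Small shared numeric helpers."""

from __future__ import annotations

import decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as results tables conventionally do.

    Python's built-in ``round`` uses bankers' rounding (81.25 → 81.2); the
    reported percentages and rates here follow the half-up convention
    (81.25 → 81.3).
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
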
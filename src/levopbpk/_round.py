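"""Decimal reporting helpers.

Published PK tables round half-up (12.95 -> 13.0, 22.85 -> 22.9); binary
floats can sit a hair below the printed half, so rounding goes through
``decimal`` on the shortest repr rather than the raw float.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
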
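"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as analytical reports do.

    Python's built-in ``round`` uses banker's rounding, which disagrees
    with how laboratory tables are conventionally rounded (e.g. 16.55 %
    reports as 16.6 %, not 16.5 %). Operates on the shortest decimal
    representation of ``x`` so that values such as 0.5975 stored as
    0.59749999...964 still round to 0.598.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def check_finite_nonnegative(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def check_positive(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")
    return value
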
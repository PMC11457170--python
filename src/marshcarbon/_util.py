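"""Small internal helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, as spreadsheets do.

    Published report tables were produced with half-up rounding, which differs
    from Python's banker's rounding on exact halves; all rendered (as opposed
    to accounting) figures go through this helper.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def require_positive(name: str, value: float) -> float:
    value = require_finite(name, value)
    if value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")
    return value


def require_non_negative(name: str, value: float) -> float:
    value = require_finite(name, value)
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return value
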
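"""Small shared helpers (display rounding)."""

from decimal import ROUND_HALF_UP, Decimal


def pct_half_up(numerator: float, denominator: float, digits: int = 2) -> float:
    """100*numerator/denominator rounded half-up to ``digits`` decimals.

    Percentages are displayed with conventional commercial rounding rather
    than banker's rounding, so 48.505 -> 48.51 and 34.375 -> 34.38.  Integer
    inputs are divided exactly under :class:`~decimal.Decimal` to avoid
    binary-float ties landing on the wrong side.
    """
    if denominator == 0:
        return 0.0
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


def round_half_up(value: float, digits: int = 2) -> float:
    """Round a plain value half-up to ``digits`` decimals."""
    q = Decimal(str(value))
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))
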
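"""Small shared helpers (rounding, percent formatting)."""

from decimal import ROUND_HALF_UP, Decimal

from .errors import DataError


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round to `decimals` places with ties going away from zero.

    Printed survey tables conventionally round 56.935 -> 56.94, which is not
    what banker's rounding (Python's built-in ``round``) does.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-up, e.g. percent(1704, 1918) == 88.84."""
    if denominator == 0:
        raise DataError("percentage undefined for a zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
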
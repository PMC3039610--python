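"""Small shared helpers: exact percent rounding, reverse complement."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_RC = str.maketrans("ACGTN", "TGCAN")


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


class PipelineError(RuntimeError):
    """Inconsistent inputs between pipeline stages."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def percent(numerator: int, denominator: int, ndigits: int) -> float:
    """Percentage numerator/denominator*100, rounded half up to `ndigits`.

    Uses exact decimal arithmetic so that boundary cases like 34.15 -> 34.2
    round deterministically (round-half-up, not banker's rounding).
    Returns 0.0 for an empty denominator.
    """
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def round_half_up(x: float, ndigits: int) -> float:
    return float(
        Decimal(repr(x)).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    )
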
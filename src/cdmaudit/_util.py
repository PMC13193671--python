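"""Shared numeric helpers: exact percentage rounding and largest-remainder apportionment."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence


def round_half_up(value: float | Decimal, ndigits: int = 1) -> float:
    """Round with ties going away from zero (half-up), as printed clinical tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100*numerator/denominator rounded half-up, computed on exact rationals.

    Half-up one-decimal rounding reproduces printed fractions such as
    5/39 -> 12.8 and 7/39 -> 17.9.
    """
    if denominator <= 0:
        raise ZeroDivisionError("percentage denominator must be positive")
    q = Decimal(1).scaleb(-ndigits)
    exact = Decimal(100 * numerator) / Decimal(denominator)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


def largest_remainder(shares: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``shares``.

    Floors each exact quota, then hands the remaining units to the largest
    fractional parts (ties broken by position). Guarantees the result sums to
    ``total`` and each count is within 1 of its exact quota.
    """
    if total < 0:
        raise ValueError("total must be nonnegative")
    s = float(sum(shares))
    if s <= 0:
        raise ValueError("shares must have a positive sum")
    quotas = [share / s * total for share in shares]
    counts = [int(q) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(range(len(shares)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def scaled_count(full_count: int, scale: float) -> int:
    """Nearest-integer scaling of a printed count; always within +-1 of scale*full."""
    return int(round_half_up(full_count * scale, 0))
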
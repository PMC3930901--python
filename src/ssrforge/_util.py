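"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def percent_half_up(numerator: float, denominator: float, ndigits: int = 1) -> float | None:
    """100 * numerator / denominator, rounded half-up to ``ndigits``.

    Returns None for a zero denominator (emitted as a blank cell).
    """
    if denominator == 0:
        return None
    q = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up(value: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
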
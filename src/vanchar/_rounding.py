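"""Half-away-from-zero decimal rounding used for all reported quantities.

Binary floats round half-cases unpredictably under ``round()`` (banker's
rounding); characterization tables conventionally round half away from
zero, so reported masses and percentages go through :func:`round_half_away`.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, half-cases away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if value == 0:
        return 0.0
    d = Decimal(repr(value))
    shift = sig - d.adjusted() - 1
    quantum = Decimal(1).scaleb(-shift)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))
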
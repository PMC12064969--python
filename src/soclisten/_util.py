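"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float | int | Decimal, decimals: int = 0) -> float:
    """Round with ties going away from zero at ``decimals`` places.

    Banker's rounding (Python's built-in) would send 0.5 to 0; descriptive
    tables in this field conventionally print half-up values, so we use
    decimal arithmetic to avoid float-representation surprises.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))
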
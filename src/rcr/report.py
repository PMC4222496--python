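"""Numeric formatting helpers for reports (2-significant-figure p-values)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_sig(x: float, ndigits: int = 2) -> float:
    """Round to *ndigits* significant figures with decimal half-up ties.

    Decimal half-up matches how the published mechanism tables print
    p-values (e.g. 0.0625 renders as 6.3E-02, not 6.2E-02).
    """
    if x == 0 or ndigits < 1:
        return 0.0
    d = Decimal(repr(float(x)))
    quantum = Decimal(1).scaleb(d.adjusted() - ndigits + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def format_sci(x: float, ndigits: int = 2) -> str:
    """Render a p-value as e.g. ``6.3E-02`` (2 significant figures, half-up)."""
    if x == 0:
        return "0.0E+00"
    r = round_sig(x, ndigits)
    mant, exp = f"{r:.{ndigits - 1}e}".split("e")
    return f"{mant}E{int(exp):+03d}"
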
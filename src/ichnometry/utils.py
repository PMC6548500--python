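"""Small shared helpers (report rounding and formatting)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of the published tables.

    Python's built-in ``round`` is banker's rounding, which disagrees with
    the printed cells on exact halves (e.g. 147.955 -> 147.96, not 147.95).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: Optional[float], ndigits: int = 2) -> str:
    if x is None:
        return "-"
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def fmt_pm(mean: Optional[float], sd: Optional[float], ndigits: int = 2) -> str:
    """Format ``mean ± SD`` with 'n/a' for the single-member case."""
    if mean is None:
        return "-"
    if sd is None:
        return f"{fmt(mean, ndigits)} ± n/a"
    return f"{fmt(mean, ndigits)} ± {fmt(sd, ndigits)}"
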
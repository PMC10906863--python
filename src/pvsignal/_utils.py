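"""Small shared helpers (rounding conventions, string normalization)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching how regulatory tables are printed.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention of published percentage tables on exact ties.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denominator: int, ndigits: int = 2) -> float:
    """Exact percentage ``100 * count / denominator`` rounded half-up.

    Computed in rational arithmetic so the printed two-decimal value is the
    correctly rounded value of the integer division, never a float artefact.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Fraction(100 * count, denominator)
    q = Decimal(10) ** -ndigits
    return float(
        (Decimal(frac.numerator) / Decimal(frac.denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def norm_text(s: str) -> str:
    """Trim, collapse internal whitespace and casefold for matching.

    Stored values stay verbatim; this is only the comparison key.
    """
    return " ".join(s.split()).casefold()


def fmt_number(x: float | int | None) -> str:
    """Render a number compactly for delimited text output."""
    if x is None:
        return ""
    if isinstance(x, int):
        return str(x)
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))
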
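"""Half-up decimal rounding used for all printed percentages.

Python's built-in ``round`` is banker's rounding; cohort tables in this
toolkit print percentages rounded half-up to two decimals (33.33, 91.18),
so rounding goes through :mod:`decimal` with an exact integer ratio
whenever one is available.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_half_up(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up from the exact ratio.

    Exact rational arithmetic avoids float artefacts at the .xx5 boundary.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set is undefined")
    frac = Fraction(100 * numerator, denominator)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
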
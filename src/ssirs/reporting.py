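"""Report bookkeeping: the fixed numeric formats used in summaries.

Every percentage the pipeline prints goes through :func:`percent` so that
summary tables, group accounting, and calibration reports all share one
rounding convention (one decimal place).
"""

from __future__ import annotations


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """100 * numerator / denominator, rounded to ``digits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, digits)


def proportion_summary(numerator: int, denominator: int) -> dict:
    """Counts plus the formatted percentage, the shape used across reports."""
    return {
        "numerator": int(numerator),
        "denominator": int(denominator),
        "pct": percent(numerator, denominator),
    }
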
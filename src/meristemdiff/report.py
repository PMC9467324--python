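"""Small reporting helpers used by the pipeline summary.

These are the arithmetic used for every headline figure the summary prints
(shares of expressed genes, ratios of selected term counts), kept in one
place so summaries and reports agree on rounding.
"""

from __future__ import annotations

__all__ = ["percent", "ratio"]


def percent(part: float, whole: float, digits: int = 0) -> float:
    """``part`` as a percentage of ``whole``, rounded to ``digits`` decimals.

    >>> percent(16842, 39809)
    42.0
    """
    if whole == 0:
        raise ZeroDivisionError("percent of an empty whole")
    return round(100.0 * part / whole, digits)


def ratio(numerator: float, denominator: float, digits: int = 1) -> float:
    """Plain rounded ratio.

    >>> ratio(27, 10)
    2.7
    """
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    return round(numerator / denominator, digits)
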
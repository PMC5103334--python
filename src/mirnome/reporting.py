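"""Small reporting helpers for dataset-level summary figures."""

from __future__ import annotations


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A share expressed as a percentage, rounded for reporting.

    The convention used for dataset summaries: 100 * numerator / denominator
    rounded to ``decimals`` places (one decimal by default).
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    return round(100.0 * numerator / denominator, decimals)


__all__ = ["percentage"]
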
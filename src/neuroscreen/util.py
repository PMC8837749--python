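"""Small shared helpers."""

from __future__ import annotations


def percent_decrease(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after`` (positive = reduction).

    The convention used to summarise rescue effects, e.g. a drop in
    aggregates per cell from 8.0 to 4.0 is a 50% decrease.
    """
    if before == 0:
        raise ValueError("percent decrease undefined for a zero baseline")
    return 100.0 * (before - after) / before
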
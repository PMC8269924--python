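"""Statistical disclosure control for published counts (HESA rounding rules).

Counts of 0, 1 or 2 are published as 0 and every other count is rounded to
the nearest multiple of 5; percentages with an unrounded base below 22.5
persons and averages over seven or fewer persons are suppressed.  Disclosure
is a presentation-boundary step only: every internal computation uses the
raw, unrounded values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SUPPRESSED",
    "DisclosureRules",
    "round_count",
    "disclose_percentage",
    "disclose_average",
    "disclose_table",
]

#: Marker emitted for suppressed cells.
SUPPRESSED = "~"


@dataclass(frozen=True)
class DisclosureRules:
    small_values: frozenset = frozenset({0, 1, 2})
    rounding_base: int = 5
    percentage_suppression_threshold: float = 22.5
    average_suppression_threshold: int = 7

    def __post_init__(self):
        if self.rounding_base < 1:
            raise ValueError("rounding_base must be >= 1")
        if self.percentage_suppression_threshold <= 0:
            raise ValueError("percentage_suppression_threshold must be positive")
        if self.average_suppression_threshold <= 0:
            raise ValueError("average_suppression_threshold must be positive")


DEFAULT_RULES = DisclosureRules()


def round_count(n: int, rules: DisclosureRules = DEFAULT_RULES) -> int:
    """Disclose a count: small values to 0, else nearest multiple of 5.

    Only nonnegative integers are accepted (counts are integers; for them
    the nearest multiple is unique).
    """
    if isinstance(n, (bool, np.bool_)) or not isinstance(n, (int, np.integer)):
        raise ValueError(f"count must be an integer, got {n!r}")
    if n < 0:
        raise ValueError(f"count must be nonnegative, got {n}")
    if n in rules.small_values:
        return 0
    base = rules.rounding_base
    return int(base * round(n / base))


def disclose_percentage(
    numerator: float, denominator: float, rules: DisclosureRules = DEFAULT_RULES
):
    """Percentage to one decimal, or the suppression marker.

    Suppression applies when the *unrounded* base is below the threshold
    (22.5 persons); a zero base is suppressed rather than raising.
    """
    if denominator < 0:
        raise ValueError("denominator must be nonnegative")
    if denominator < rules.percentage_suppression_threshold:
        return SUPPRESSED
    return round(100.0 * numerator / denominator, 1)


def disclose_average(values, rules: DisclosureRules = DEFAULT_RULES):
    """Arithmetic mean, suppressed when based on too few individuals."""
    values = list(values)
    if len(values) <= rules.average_suppression_threshold:
        return SUPPRESSED
    return float(np.mean(values))


def disclose_table(
    counts: pd.DataFrame,
    count_columns: list[str] | None = None,
    rules: DisclosureRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Disclosed twin of a counts table.

    Every cell in ``count_columns`` (default: all integer columns) is passed
    through :func:`round_count`.  Cells that cannot be disclosed are marked
    with the suppression marker.
    """
    out = counts.copy()
    if count_columns is None:
        count_columns = [
            c for c in counts.columns if pd.api.types.is_integer_dtype(counts[c])
        ]
    for col in count_columns:
        out[col] = [
            round_count(int(v), rules) if pd.notna(v) else SUPPRESSED
            for v in counts[col]
        ]
    return out
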
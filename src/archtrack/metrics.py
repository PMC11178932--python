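"""Detection/tracking evaluation arithmetic.

Precision and recall come from raw per-session tallies (TP/FP/FN; TN is
carried for table compatibility but enters neither formula). Session tables
are summarised by an unweighted macro-average, with both conventional
rounding and truncation supported because published summary figures follow
one or the other depending on the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "MetricCounts",
    "precision",
    "recall",
    "detection_accuracy",
    "macro_average",
    "load_reference_table",
]


@dataclass(frozen=True)
class MetricCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def _round_half_up(x: float, digits: int) -> float:
    scale = 10**digits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _truncate(x: float, digits: int) -> float:
    scale = 10**digits
    return math.trunc(x * scale) / scale


def precision(c: MetricCounts, digits: int = 2) -> float:
    """100 * TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("precision undefined: no positive predictions")
    return _round_half_up(100.0 * c.tp / (c.tp + c.fp), digits)


def recall(c: MetricCounts, digits: int = 2) -> float:
    """100 * TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("recall undefined: no positive cases")
    return _round_half_up(100.0 * c.tp / (c.tp + c.fn), digits)


def detection_accuracy(
    c: MetricCounts,
    mode: Literal["primary", "sheet_compat"] = "primary",
    digits: int = 2,
) -> float:
    """Detection accuracy from counts.

    ``primary``: 100 * TP / (TP + FP + FN), the natural definition for a
    detection task without true negatives. ``sheet_compat`` reproduces
    evaluation sheets whose accuracy column duplicates precision even when
    misses are present.
    """
    if mode == "sheet_compat":
        return precision(c, digits)
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ZeroDivisionError("accuracy undefined: all counts zero")
    return _round_half_up(100.0 * c.tp / denom, digits)


def macro_average(
    values: Sequence[float],
    rounding: Literal["round", "truncate"] = "round",
    digits: int = 2,
) -> float:
    """Unweighted mean of per-session percentages, then round or truncate."""
    if len(values) == 0:
        raise ValueError("macro_average of empty list")
    mean = sum(values) / len(values)
    return _truncate(mean, digits) if rounding == "truncate" else _round_half_up(mean, digits)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the bundled per-session evaluation tally sheets.

    Available: ``detection_counts`` (28 sessions: instances, TP, FP, FN),
    ``detector_comparison`` (two detectors on one session),
    ``tracking_counts`` (28 sessions: cattle, correct, wrong),
    ``classifier_sessions`` (19 sessions x 5 classifiers, accuracy %).
    """
    ref = resources.files("archtrack.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
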
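"""Semiquantitative immunohistochemistry scoring and expression-rate analysis.

Each specimen gets a staining-intensity score (0-3) and a positive-cell
percentage score (0-4); the specimen is positive when the product of the two
exceeds 3 (strictly). Expression tables cross-tabulate specimens by tissue
group (lesional / perilesional / normal) or by differentiation grade against
the negative/positive outcome, and group differences are tested with the
Pearson chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .diagstats import chi_square_test, round_half_up

__all__ = [
    "IHCScore",
    "score_specimen",
    "expression_table",
    "positive_rate",
    "compare_expression",
    "grade_stratified_rates",
]

Marker = Literal["EZH2", "p57"]
POSITIVITY_THRESHOLD = 3  # product must be STRICTLY greater


@dataclass(frozen=True)
class IHCScore:
    marker: Marker
    intensity_score: int
    percent_score: int
    product: int = field(init=False)
    positive: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_score <= 3:
            raise ValueError(f"intensity score must be in [0, 3], got {self.intensity_score}")
        if not 0 <= self.percent_score <= 4:
            raise ValueError(f"percent score must be in [0, 4], got {self.percent_score}")
        product = self.intensity_score * self.percent_score
        object.__setattr__(self, "product", product)
        object.__setattr__(self, "positive", product > POSITIVITY_THRESHOLD)


def score_specimen(marker: Marker, intensity_score: int, percent_score: int) -> IHCScore:
    """Score one specimen; positive iff intensity x percentage product > 3."""
    return IHCScore(marker, intensity_score, percent_score)


def expression_table(specimens: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Cross-tabulate per-specimen ``positive`` flags into a counts table.

    ``specimens`` needs a boolean ``positive`` column and the grouping
    column ``by``. Returns a frame indexed by group with ``negative`` and
    ``positive`` count columns, preserving first-appearance group order.
    """
    if by not in specimens.columns:
        raise ValueError(f"missing grouping column {by!r}")
    order = specimens[by].drop_duplicates().tolist()
    counts = (
        specimens.groupby(by, sort=False)["positive"]
        .agg(negative=lambda s: int((~s.astype(bool)).sum()), positive=lambda s: int(s.sum()))
        .reindex(order)
    )
    counts.index.name = by
    return counts.astype(int)


def positive_rate(table: pd.DataFrame, group: str) -> float:
    """Positive expression rate of one group as a percentage (2 decimals)."""
    if group not in table.index:
        raise ValueError(f"group {group!r} not in table")
    row = table.loc[group]
    total = int(row["negative"] + row["positive"])
    if total == 0:
        raise ValueError(f"group {group!r} has no specimens")
    return round_half_up(100 * row["positive"] / total)


def compare_expression(table: pd.DataFrame) -> tuple[float, float]:
    """Chi-square test of independence across the table's groups."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 groups to compare")
    stat, p, _ = chi_square_test(table[["negative", "positive"]].to_numpy())
    return stat, p


def grade_stratified_rates(
    scores: Sequence[IHCScore] | pd.DataFrame,
    grades: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-grade expression tables for each marker.

    Accepts either a specimen DataFrame with columns ``marker``, ``grade``,
    ``positive``, or a sequence of :class:`IHCScore` with a parallel
    ``grades`` sequence. Every specimen must carry a grade.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores
    else:
        if grades is None or len(grades) != len(scores):
            raise ValueError("grades must be given, one per score")
        df = pd.DataFrame(
            {
                "marker": [s.marker for s in scores],
                "grade": list(grades),
                "positive": [s.positive for s in scores],
            }
        )
    if df["grade"].isna().any() or (df["grade"] == "").any():
        raise ValueError("every specimen must carry a differentiation grade")
    out: dict[str, pd.DataFrame] = {}
    for marker, sub in df.groupby("marker", sort=False):
        tab = expression_table(sub, by="grade")
        tab["rate_percent"] = [
            round_half_up(100 * p / (p + n)) if (p + n) else np.nan
            for n, p in zip(tab["negative"], tab["positive"])
        ]
        out[str(marker)] = tab
    return out
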
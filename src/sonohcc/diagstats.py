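"""Diagnostic-performance and association statistics.

Builds diagnosis-vs-pathology 2x2 tables (malignant is the positive class,
pathology biopsy is the gold standard) and computes sensitivity,
specificity, accuracy, Cohen's kappa with its clinical interpretation bands
(poor < 0.45 <= good < 0.70 <= satisfactory), Pearson chi-square and
Fisher's exact tests, and per-grade imaging-feature frequency tables.

Percentages are rounded half-up to two decimals for display parity with
clinical reporting; raw fractions are always available.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .modality import ModalityCall

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticSummary",
    "round_half_up",
    "build_contingency",
    "diagnostic_performance",
    "cohen_kappa",
    "kappa_band",
    "chi_square_test",
    "fisher_exact_test",
    "feature_frequency_table",
]

KappaBand = Literal["poor", "good", "satisfactory"]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Diagnosis-vs-pathology counts; malignant is the positive class."""

    tp: int  # called malignant, pathology malignant
    fp: int  # called malignant, pathology benign
    fn: int  # called benign, pathology malignant
    tn: int  # called benign, pathology benign

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class DiagnosticSummary:
    """Percent statistics (2 decimals) plus the underlying raw fractions."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float
    kappa: float | None
    kappa_band: KappaBand | None
    raw_sensitivity: float | None
    raw_specificity: float | None
    raw_accuracy: float


def build_contingency(
    calls: Sequence[ModalityCall | str],
    truth: Sequence[str],
) -> ContingencyTable2x2:
    """Cross-tabulate diagnostic calls against pathology labels."""
    if len(calls) != len(truth):
        raise ValueError(f"{len(calls)} calls vs {len(truth)} truth labels")
    tp = fp = fn = tn = 0
    for call, label in zip(calls, truth):
        verdict = call.verdict if isinstance(call, ModalityCall) else call
        if verdict not in ("benign", "malignant") or label not in ("benign", "malignant"):
            raise ValueError(f"labels must be benign/malignant, got {verdict!r}/{label!r}")
        if verdict == "malignant":
            if label == "malignant":
                tp += 1
            else:
                fp += 1
        else:
            if label == "malignant":
                fn += 1
            else:
                tn += 1
    return ContingencyTable2x2(tp, fp, fn, tn)


def kappa_band(kappa: float) -> KappaBand:
    if kappa >= 0.70:
        return "satisfactory"
    if kappa >= 0.45:
        return "good"
    return "poor"


def cohen_kappa(t: ContingencyTable2x2) -> tuple[float | None, KappaBand | None]:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)`` from the margins.

    Returns ``(None, None)`` when the margins are degenerate (``p_e`` = 1).
    """
    n = t.total
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = (t.tp + t.tn) / n
    row_pos, row_neg = t.tp + t.fp, t.fn + t.tn
    col_pos, col_neg = t.tp + t.fn, t.fp + t.tn
    p_e = (row_pos * col_pos + row_neg * col_neg) / (n * n)
    if p_e == 1.0:
        return None, None
    kappa = (p_o - p_e) / (1 - p_e)
    return kappa, kappa_band(kappa)


def diagnostic_performance(t: ContingencyTable2x2) -> DiagnosticSummary:
    """Sensitivity, specificity, accuracy (percent, 2 dp) and kappa for a table.

    A statistic whose denominator is zero is reported as ``None`` rather
    than 0.
    """
    if t.total == 0:
        raise ValueError("empty contingency table")
    sens = t.tp / (t.tp + t.fn) if (t.tp + t.fn) > 0 else None
    spec = t.tn / (t.tn + t.fp) if (t.tn + t.fp) > 0 else None
    acc = (t.tp + t.tn) / t.total
    kappa, band = cohen_kappa(t)
    return DiagnosticSummary(
        sensitivity=None if sens is None else round_half_up(100 * sens),
        specificity=None if spec is None else round_half_up(100 * spec),
        accuracy=round_half_up(100 * acc),
        kappa=None if kappa is None else round_half_up(kappa),
        kappa_band=band,
        raw_sensitivity=sens,
        raw_specificity=spec,
        raw_accuracy=acc,
    )


def chi_square_test(
    table: np.ndarray | Sequence[Sequence[int]],
    *,
    correction: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Pearson chi-square on an r x c count grid.

    Returns ``(statistic, p_value, expected_counts)``. Continuity correction
    is off by default. Zero-margin rows or columns are rejected.
    """
    grid = np.asarray(table, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("need at least a 2x2 grid of counts")
    if np.any(grid.sum(axis=0) == 0) or np.any(grid.sum(axis=1) == 0):
        raise ValueError("table has a zero-margin row or column")
    stat, p, _, expected = spstats.chi2_contingency(grid, correction=correction)
    return float(stat), float(p), expected


def fisher_exact_test(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    _, p = spstats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


# Binary feature attributes tabulated per grade: (column, category counted).
_BINARY_FEATURES: list[tuple[str, str]] = [
    ("shape", "irregular"),
    ("boundary", "unclear"),
    ("internal_echo", "inhomogeneous"),
    ("posterior_echo", "unchanged_or_enhanced"),
]

GRADE_ORDER = ("poor", "moderate", "high")


def feature_frequency_table(lesions: pd.DataFrame) -> pd.DataFrame:
    """Per-grade counts and percentages of each imaging feature.

    ``lesions`` needs columns ``pathology``, ``grade`` and the findings
    columns (``shape``, ``boundary``, ``internal_echo``, ``posterior_echo``,
    ``flow_grade``, ``elasticity_score``, ``ceus_pattern``). Only malignant
    lesions are tabulated; an ungraded malignant lesion is an error.

    Returns a tidy frame with one row per (grade, feature): columns
    ``grade``, ``feature``, ``n_lesions``, ``count``, ``percent``.
    """
    mal = lesions[lesions["pathology"] == "malignant"]
    if mal["grade"].isna().any():
        raise ValueError("malignant lesion without differentiation grade")
    rows = []
    for grade, sub in mal.groupby("grade", sort=False):
        n = len(sub)
        feats: list[tuple[str, int]] = [
            (f"{col}={cat}", int((sub[col] == cat).sum())) for col, cat in _BINARY_FEATURES
        ]
        feats.append(("flow_grade=2-3", int(sub["flow_grade"].isin([2, 3]).sum())))
        feats.append(
            ("elasticity_score=4-5", int(sub["elasticity_score"].isin([4, 5]).sum()))
        )
        feats.append(("ceus_pattern=FFFO", int((sub["ceus_pattern"] == "FFFO").sum())))
        for name, count in feats:
            rows.append(
                {
                    "grade": grade,
                    "feature": name,
                    "n_lesions": n,
                    "count": count,
                    "percent": round_half_up(100 * count / n) if n else float("nan"),
                }
            )
    out = pd.DataFrame(rows)
    order = {g: i for i, g in enumerate(GRADE_ORDER)}
    return out.sort_values(
        by="grade", key=lambda s: s.map(order), kind="stable"
    ).reset_index(drop=True)
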
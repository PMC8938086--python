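"""Segmentation-quality evaluation: VOE, gold-standard selection, confusion
metrics, and average precision.

VOE (volumetric overlap error) is 1 minus the Jaccard overlap of two binary
masks. Among a set of annotator masks, the "gold standard" is the member with
the smallest mean VOE against the others. Average precision is the
trapezoidal area under an explicit precision-recall point list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "voe",
    "select_gold_standard",
    "confusion_counts",
    "classification_metrics",
    "average_precision",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1, 255))):
        raise ValueError("mask values must be binary ({0,1} or {0,255})")
    return arr > 0


def voe(a: np.ndarray, b: np.ndarray) -> float:
    """Volumetric overlap error ``1 - |a AND b| / |a OR b|`` in [0, 1].

    Two empty masks are defined as identical (VOE 0) with a warning.
    """
    ma, mb = _as_bool_mask(a), _as_bool_mask(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        warnings.warn("VOE of two empty masks defined as 0", stacklevel=2)
        return 0.0
    inter = np.logical_and(ma, mb).sum()
    return float(1.0 - inter / union)


def select_gold_standard(masks: Sequence[np.ndarray]) -> tuple[int, np.ndarray]:
    """Pick the most mutually consistent annotation from a set.

    Returns ``(index, mask)`` of the member with minimal mean VOE against all
    other members; ties go to the lowest annotator index.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 annotations to select a gold standard")
    k = len(masks)
    pairwise = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pairwise[i, j] = pairwise[j, i] = voe(masks[i], masks[j])
    mean_voe = pairwise.sum(axis=1) / (k - 1)
    best = int(np.argmin(mean_voe))  # argmin takes the first minimum: lowest index wins
    return best, masks[best]


def confusion_counts(pred: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted mask against the gold mask."""
    mp, mg = _as_bool_mask(pred), _as_bool_mask(gold)
    if mp.shape != mg.shape:
        raise ValueError(f"mask shapes differ: {mp.shape} vs {mg.shape}")
    return ConfusionCounts(
        tp=int(np.sum(mp & mg)),
        fp=int(np.sum(mp & ~mg)),
        fn=int(np.sum(~mp & mg)),
        tn=int(np.sum(~mp & ~mg)),
    )


def classification_metrics(
    c: ConfusionCounts,
) -> tuple[float, float | None, float | None]:
    """Return ``(accuracy, precision, recall)``.

    Precision is ``None`` when no positives were predicted (TP+FP = 0) and
    recall is ``None`` when no positives exist (TP+FN = 0); undefined ratios
    are flagged rather than reported as 0.
    """
    if c.total <= 0:
        raise ValueError("empty confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return accuracy, precision, recall


def average_precision(curve: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an explicit precision-recall point list.

    ``curve`` is an ordered sequence of ``(recall_i, precision_i)`` pairs with
    non-decreasing recall:

        AP = 1/2 * sum_i (R_{i+1} - R_i) (P_{i+1} + P_i)
    """
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("curve must be a sequence of >= 2 (recall, precision) pairs")
    recall, precision = pts[:, 0], pts[:, 1]
    if np.any((recall < 0) | (recall > 1)) or np.any((precision < 0) | (precision > 1)):
        raise ValueError("recall and precision must lie in [0, 1]")
    if np.any(np.diff(recall) < 0):
        raise ValueError("recall must be non-decreasing along the curve")
    ap = 0.5 * float(np.sum(np.diff(recall) * (precision[1:] + precision[:-1])))
    return ap
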
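"""Precision-recall machinery: AUPRC, precision at fixed recall, top F1,
and recall-calibrated threshold selection.

The decision rule throughout is ``score > alpha``.  The curve has one
operating point per distinct score value (ties enter or leave the positive
set together); the lowest distinct score yields the recall = 1 endpoint.
AUPRC uses right-continuous step integration (sum of precision times recall
increment), which avoids the optimism of trapezoidal interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_TARGET_RECALL = 0.95


@dataclass
class PRCurve:
    """Operating points sorted by descending threshold.

    Point i corresponds to predicting positive exactly the items with
    ``score >= thresholds[i]`` (i.e. the rule ``score > alpha`` for any alpha
    just below ``thresholds[i]``).
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_pos: int
    n_neg: int

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"threshold": self.thresholds,
                      "precision": self.precision,
                      "recall": self.recall}).to_csv(path, index=False)


@dataclass
class MetricsReport:
    auprc: float
    precision_at_recall: float
    target_recall: float
    best_f1: float
    n_pos: int
    n_neg: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    return s, y.astype(int)


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall operating points, one per distinct score (descending)."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp_cum = np.cumsum(y_sorted)
    pred_cum = np.arange(1, len(y) + 1)
    # last index of each distinct-score group = the grouped-ties operating point
    is_last = np.empty(len(s), dtype=bool)
    is_last[:-1] = s_sorted[:-1] != s_sorted[1:]
    is_last[-1] = True
    idx = np.flatnonzero(is_last)
    return PRCurve(thresholds=s_sorted[idx],
                   precision=tp_cum[idx] / pred_cum[idx],
                   recall=tp_cum[idx] / n_pos,
                   n_pos=n_pos, n_neg=n_neg)


def auprc(curve: PRCurve) -> float:
    """Area under the PR curve by right-continuous step integration."""
    r = np.concatenate([[0.0], curve.recall])
    return float(np.sum(curve.precision * np.diff(r)))


def precision_at_recall(curve: PRCurve,
                        target: float = DEFAULT_TARGET_RECALL) -> float:
    """Maximum precision over operating points with recall >= target."""
    mask = curve.recall >= target
    if not mask.any():  # recall=1 endpoint always exists, so target <= 1 qualifies
        raise ValueError(f"no operating point reaches recall {target}")
    return float(curve.precision[mask].max())


def best_f1(curve: PRCurve) -> float:
    """Top F1 = max over operating points of the harmonic mean of p and r."""
    p, r = curve.precision, curve.recall
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return float(f1.max())


def evaluate(scores, labels,
             target_recall: float = DEFAULT_TARGET_RECALL) -> MetricsReport:
    """AUPRC, precision at the target recall, and top F1 in one report."""
    curve = pr_curve(scores, labels)
    return MetricsReport(auprc=auprc(curve),
                         precision_at_recall=precision_at_recall(curve, target_recall),
                         target_recall=target_recall,
                         best_f1=best_f1(curve),
                         n_pos=curve.n_pos, n_neg=curve.n_neg)


def calibrate_threshold(scores, labels,
                        target_recall: float = DEFAULT_TARGET_RECALL) -> float:
    """Largest threshold alpha whose recall >= target under ``score > alpha``.

    With n_pos positives, recall >= target requires admitting at least
    ``k = ceil(target * n_pos)`` positives, so alpha must lie strictly below
    the k-th largest positive score s_k.  We return the midpoint between s_k
    and the next distinct score below it (over all scores); if s_k is the
    global minimum, a small offset below s_k.
    """
    s, y = _validate(scores, labels)
    pos = s[y == 1]
    if len(pos) == 0:
        raise ValueError("calibration requires at least one positive")
    k = int(np.ceil(target_recall * len(pos)))
    k = max(k, 1)
    s_k = np.sort(pos)[::-1][k - 1]
    below = s[s < s_k]
    if len(below):
        return float((s_k + below.max()) / 2.0)
    return float(s_k - 1e-9 * max(1.0, abs(s_k)))
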
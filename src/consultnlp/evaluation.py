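"""ROC analysis, bootstrap confidence intervals, and operating thresholds.

The operating threshold for each concept classifier maximizes Youden's J
(sensitivity + specificity - 1) over the candidate thresholds implied by
the score distribution; the classification rule everywhere in the package
is ``score >= threshold -> positive``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "RocCurve",
    "DiagnosticReport",
    "roc_auc",
    "compute_roc_curve",
    "bootstrap_auc_ci",
    "youden_threshold",
    "binary_diagnostics",
]


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D vectors of equal length")
    return scores, labels


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve as (FPR, TPR) points with its trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion counts and derived metrics at one operating threshold.

    Ratios with zero denominators are ``None`` (explicitly unset), never
    silently 0 or 1.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
        }


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney statistic P(score+ > score-) + 0.5 P(tie).
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    return float(roc_auc_score(labels, scores))


def compute_roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(np.trapezoid(tpr, fpr)))


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Positives and negatives are resampled separately with replacement so
    every replicate retains both classes even at 0.3% prevalence.
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    if replicates < 100:
        logger.warning("bootstrap with %d replicates; intervals will be unstable", replicates)
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    aucs = np.empty(replicates)
    ones = np.ones(len(pos), dtype=bool)
    zeros = np.zeros(len(neg), dtype=bool)
    lab = np.concatenate([ones, zeros])
    for b in range(replicates):
        sample = np.concatenate([rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))])
        aucs[b] = roc_auc_score(lab, sample)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Distinct-score midpoints plus the minimum score (everything positive)."""
    distinct = np.unique(scores)
    if len(distinct) == 1:
        return distinct
    mid = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0]], mid])


def youden_threshold(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct scores (plus the
    minimum score itself); ties are broken toward the lower threshold,
    which favors sensitivity for screening use.
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_thr = None
    best_j = -np.inf
    for thr in _candidate_thresholds(scores):  # ascending: first max wins ties
        pred = scores >= thr
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_thr = thr
    return float(best_thr)


def binary_diagnostics(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> DiagnosticReport:
    """Confusion counts and metrics at ``score >= threshold -> positive``."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return DiagnosticReport(threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn)
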
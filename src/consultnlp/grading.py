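"""Consultation-level quality grading via top-K sentence extraction.

The actual quality score of a consultation for a concept is the maximum
0-5 grade over all of its sentences.  The model-predicted score is the
maximum grade over only the K sentences with the highest predicted
probability of topic concordance — so the predicted score can never
exceed the actual score, and reaches it exactly once K covers the whole
consultation.  Agreement between the two is summarized per concept with a
6x6 confusion matrix and micro-averaged one-vs-rest metrics over the
fixed six ordinal levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .concepts import Concept
from .corpus_io import Corpus, LabeledSentence

__all__ = [
    "QUALITY_LEVELS",
    "QUANTIFICATION_FLOOR",
    "ConsultGrade",
    "AgreementReport",
    "KSensitivityResult",
    "actual_consult_score",
    "top_k_indices",
    "predicted_consult_score",
    "grade_consults",
    "multiclass_agreement",
    "k_sensitivity",
    "capture_rate",
    "probability_quality_regression",
]

#: Default level descriptions.  Only the printed anchors are fixed science
#: (0 = not mentioned, 3+ = quantified, 5 = patient-centered and
#: patient-specific); intermediate wording is configurable by the user.
QUALITY_LEVELS: dict[int, str] = {
    0: "not mentioned",
    1: "mentioned without detail",
    2: "qualitative detail only",
    3: "quantified",
    4: "quantified with context",
    5: "patient-centered, patient-specific",
}

#: Grades at or above this level count as quantified risk communication.
QUANTIFICATION_FLOOR = 3


@dataclass(frozen=True)
class ConsultGrade:
    """Actual vs. top-K predicted quality score for one (consult, concept)."""

    consult_id: str
    concept: Concept
    actual_score: int
    predicted_score: int
    k_used: int
    top_sentence_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.k_used < 1:
            raise ValueError("k_used must be >= 1")
        if self.predicted_score > self.actual_score:
            raise ValueError("predicted score cannot exceed the actual (all-sentence) score")


@dataclass(frozen=True)
class AgreementReport:
    """Multiclass agreement between actual and predicted consult scores.

    Metrics are micro-averaged one-vs-rest over a fixed ``n_levels``
    ordinal classes (including levels absent from the data), under which
    micro-sensitivity = micro-PPV = accuracy and micro-specificity =
    micro-NPV = 1 - (1 - accuracy)/(n_levels - 1).
    """

    concept: Concept | None
    confusion: np.ndarray  # actual x predicted
    n_levels: int = 6

    @property
    def n_consults(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def sensitivity(self) -> float:
        return self.accuracy

    @property
    def ppv(self) -> float:
        return self.accuracy

    @property
    def specificity(self) -> float:
        return 1.0 - (1.0 - self.accuracy) / (self.n_levels - 1)

    @property
    def npv(self) -> float:
        return self.specificity

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def per_class_metrics(self) -> dict[int, dict[str, float | None]]:
        """Secondary one-vs-rest metrics for each individual level."""
        out: dict[int, dict[str, float | None]] = {}
        total = self.confusion.sum()
        for lvl in range(self.n_levels):
            tp = self.confusion[lvl, lvl]
            fn = self.confusion[lvl, :].sum() - tp
            fp = self.confusion[:, lvl].sum() - tp
            tn = total - tp - fn - fp
            ratio = lambda a, b: float(a / b) if b > 0 else None
            out[lvl] = {
                "sensitivity": ratio(tp, tp + fn),
                "specificity": ratio(tn, tn + fp),
                "ppv": ratio(tp, tp + fp),
                "npv": ratio(tn, tn + fn),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "concept": self.concept.value if self.concept else None,
            "n_consults": self.n_consults,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class KSensitivityResult:
    """Grading accuracy per concept as a function of K."""

    ks: tuple[int, ...]
    accuracy: Mapping[Concept, tuple[float, ...]]  # aligned to ks


def actual_consult_score(sentences: Sequence[LabeledSentence], concept: Concept) -> int:
    """Max grade over all sentences of one consultation (0 if never raised)."""
    if not sentences:
        raise ValueError("consultation has no sentences")
    ids = {s.sentence.consult_id for s in sentences}
    if len(ids) != 1:
        raise ValueError(f"sentences span multiple consultations: {sorted(ids)}")
    return max(s.grades[concept] for s in sentences)


def top_k_indices(probabilities: Sequence[float], k: int) -> list[int]:
    """Indices of the k largest probabilities, descending.

    Ties break toward the earlier sentence position, so extraction is
    stable and reproducible; if fewer than k sentences exist, all are
    returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(probabilities, dtype=float)
    order = sorted(range(len(p)), key=lambda i: (-p[i], i))
    return order[: min(k, len(p))]


def predicted_consult_score(
    sentences: Sequence[LabeledSentence],
    probabilities: Sequence[float],
    k: int,
    concept: Concept,
) -> int:
    """Max grade over the top-K sentences by predicted probability."""
    if len(sentences) != len(probabilities):
        raise ValueError("probabilities must align with sentences")
    if not sentences:
        raise ValueError("consultation has no sentences")
    top = top_k_indices(probabilities, k)
    return max(sentences[i].grades[concept] for i in top)


def grade_consults(
    corpus: Corpus,
    probabilities_by_concept: Mapping[Concept, Sequence[float]],
    k: int = 10,
) -> list[ConsultGrade]:
    """Grade every (consultation, concept) pair via the top-K protocol.

    ``probabilities_by_concept`` holds one probability per corpus sentence
    (corpus order) for each concept.
    """
    groups = corpus.by_consult()
    offsets: dict[str, list[int]] = {}
    for i, s in enumerate(corpus):
        offsets.setdefault(s.sentence.consult_id, []).append(i)
    out: list[ConsultGrade] = []
    for concept, probs in probabilities_by_concept.items():
        p = np.asarray(probs, dtype=float)
        if len(p) != len(corpus):
            raise ValueError("probability vector length must equal corpus size")
        for cid, group in groups.items():
            local_p = p[offsets[cid]]
            top = top_k_indices(local_p, k)
            out.append(
                ConsultGrade(
                    consult_id=cid,
                    concept=concept,
                    actual_score=actual_consult_score(group, concept),
                    predicted_score=predicted_consult_score(group, local_p, k, concept),
                    k_used=k,
                    top_sentence_indices=tuple(group[i].sentence.index for i in top),
                )
            )
    return out


def multiclass_agreement(
    actual: Sequence[int],
    predicted: Sequence[int],
    n_levels: int = 6,
    concept: Concept | None = None,
) -> AgreementReport:
    """Confusion matrix and micro-averaged agreement over ordinal levels."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("actual and predicted must be equal-length non-empty vectors")
    if a.min() < 0 or a.max() >= n_levels or p.min() < 0 or p.max() >= n_levels:
        raise ValueError(f"scores must lie in [0, {n_levels - 1}]")
    confusion = np.zeros((n_levels, n_levels), dtype=int)
    np.add.at(confusion, (a, p), 1)
    return AgreementReport(concept=concept, confusion=confusion, n_levels=n_levels)


def k_sensitivity(
    corpus: Corpus,
    probabilities_by_concept: Mapping[Concept, Sequence[float]],
    ks: Sequence[int] = (5, 10, 15, 20),
) -> KSensitivityResult:
    """Grading accuracy for each K cutoff.

    Because the predicted score is a subset maximum, accuracy is
    non-decreasing in K for every concept.
    """
    if not ks or any(k < 1 for k in ks):
        raise ValueError("ks must be non-empty with every k >= 1")
    ks = tuple(sorted(ks))
    accuracy: dict[Concept, tuple[float, ...]] = {}
    for concept in probabilities_by_concept:
        accs = []
        for k in ks:
            grades = grade_consults(corpus, {concept: probabilities_by_concept[concept]}, k=k)
            correct = sum(g.predicted_score == g.actual_score for g in grades)
            accs.append(correct / len(grades))
        accuracy[concept] = tuple(accs)
    return KSensitivityResult(ks=ks, accuracy=accuracy)


def capture_rate(
    grades: Sequence[int],
    probabilities: Sequence[float],
    probability_cutoff: float,
    min_grade: int = QUANTIFICATION_FLOOR,
) -> float | None:
    """Fraction of quantified-risk sentences captured above a cutoff.

    Among sentences graded at or above ``min_grade``, the fraction whose
    predicted probability is *strictly* greater than the cutoff; ``None``
    if no sentence qualifies.
    """
    g = np.asarray(grades, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if g.shape != p.shape:
        raise ValueError("grades and probabilities must align")
    mask = g >= min_grade
    if not mask.any():
        return None
    return float((p[mask] > probability_cutoff).mean())


def probability_quality_regression(
    probabilities: Sequence[float], grades: Sequence[int]
) -> tuple[float, float, float]:
    """OLS of quality grade on predicted probability.

    Returns (slope, intercept, two-sided p-value for the slope).  A
    positive slope means higher-probability sentences carry higher-quality
    risk communication.
    """
    p = np.asarray(probabilities, dtype=float)
    g = np.asarray(grades, dtype=float)
    if p.shape != g.shape or len(p) < 3:
        raise ValueError("need at least 3 aligned (probability, grade) points")
    if np.ptp(p) == 0:
        raise ValueError("constant predictor: probabilities do not vary")
    X = sm.add_constant(p)
    fit = sm.OLS(g, X).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.pvalues[1])
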
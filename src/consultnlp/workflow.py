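"""End-to-end orchestration: featurize, race families, train, grade.

These functions wire the lower-level modules into the study's workflow:

1. split the development corpus 75/25 at sentence level,
2. featurize on a vocabulary fit to the training split only,
3. race the six model families by ten-fold cross-validated AUC,
4. train the champion family per concept on the full training split and
   pick each concept's operating threshold by Youden's J on the internal
   validation split,
5. score a separate consultation set and grade consultation-level quality
   via the top-K protocol.

Family racing and per-concept cross-validation run on a fixed-size random
subsample of the training split (relative rankings are stable under
subsampling, and an RBF support vector machine cannot be cross-validated
at twenty thousand sentences in reasonable time); the subsampler tops up
any concept whose positives would otherwise fall below the fold count, so
stratified folds always exist even at 0.3% prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .concepts import CONCEPTS, Concept
from .corpus_io import Corpus, split_corpus
from .evaluation import binary_diagnostics, bootstrap_auc_ci, roc_auc, youden_threshold
from .featurize import Vocabulary, build_vocabulary, vectorize
from .grading import (
    AgreementReport,
    KSensitivityResult,
    capture_rate,
    grade_consults,
    k_sensitivity,
    multiclass_agreement,
    probability_quality_regression,
)
from .models import (
    FAMILIES,
    ConceptModel,
    CvResult,
    ModelSpec,
    cross_validate,
    predict_probability,
    rank_model_families,
    train,
)

__all__ = [
    "TrainingRun",
    "GradingRun",
    "guarded_subsample",
    "run_training",
    "run_grading",
]


@dataclass
class TrainingRun:
    """Everything produced by the model-development stage."""

    train_corpus: Corpus
    validation_corpus: Corpus
    vocabulary: Vocabulary
    rankings: dict[Concept, list[CvResult]]
    champion_family: str
    champion_cv: dict[Concept, CvResult]
    models: dict[Concept, ConceptModel]
    validation_auc: dict[Concept, float]
    validation_auc_ci: dict[Concept, tuple[float, float]]
    diagnostics: dict[Concept, object]

    def ranking_table(self) -> list[dict]:
        """Family-by-concept mean CV AUCs, one row per (concept, family)."""
        rows = []
        for concept, results in self.rankings.items():
            for rank, r in enumerate(results, start=1):
                rows.append(
                    {
                        "concept": concept.value,
                        "family": r.spec.family,
                        "rank": rank,
                        "mean_auc": r.mean_auc,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                    }
                )
        return rows


@dataclass
class GradingRun:
    """Everything produced by the quality-evaluation stage."""

    corpus: Corpus
    probabilities: dict[Concept, np.ndarray]
    agreement: dict[Concept, AgreementReport]
    k_sensitivity: KSensitivityResult
    capture_rates: dict[float, float | None]
    regression: dict[Concept, tuple[float, float, float]]
    k_used: int


def guarded_subsample(
    n_rows: int,
    labels_by_concept: Mapping[Concept, np.ndarray],
    size: int,
    folds: int,
    seed: int,
) -> np.ndarray:
    """Random row subsample guaranteeing >= ``folds`` positives per concept.

    Draws uniformly, then swaps extra positives in (replacing sampled
    negatives) for any concept left short of the fold count.  Deterministic
    under seed.
    """
    rng = np.random.default_rng(seed)
    if size >= n_rows:
        return np.arange(n_rows)
    chosen = rng.choice(n_rows, size=size, replace=False)
    in_sample = np.zeros(n_rows, dtype=bool)
    in_sample[chosen] = True
    for concept, labels in labels_by_concept.items():
        labels = np.asarray(labels, dtype=bool)
        shortfall = folds - int(labels[in_sample].sum())
        if shortfall <= 0:
            continue
        outside_pos = np.flatnonzero(labels & ~in_sample)
        if len(outside_pos) < shortfall:
            raise ValueError(f"corpus has too few {concept.value}-positive sentences for {folds}-fold CV")
        add = rng.choice(outside_pos, size=shortfall, replace=False)
        # drop the same number of sampled all-negative rows to keep size
        neg_mask = in_sample.copy()
        for lab in labels_by_concept.values():
            neg_mask &= ~np.asarray(lab, dtype=bool)
        drop = rng.choice(np.flatnonzero(neg_mask), size=shortfall, replace=False)
        in_sample[drop] = False
        in_sample[add] = True
    return np.flatnonzero(in_sample)


def default_specs(seed: int) -> list[ModelSpec]:
    return [ModelSpec(family=f, seed=seed) for f in FAMILIES]


def run_training(
    corpus: Corpus,
    train_fraction: float = 0.75,
    seed: int = 0,
    families: Sequence[str] = FAMILIES,
    folds: int = 10,
    min_document_frequency: int = 2,
    race_subsample: int = 4000,
    cv_subsample: int = 6000,
    bootstrap_replicates: int = 2000,
    by_consult_split: bool = False,
) -> TrainingRun:
    """The full model-development stage on a labeled development corpus."""
    train_c, valid_c = split_corpus(corpus, train_fraction, seed=seed, by_consult=by_consult_split)
    vocab = build_vocabulary(train_c.texts(), min_document_frequency)
    Xtr = vectorize(train_c.texts(), vocab)
    Xva = vectorize(valid_c.texts(), vocab)
    labels_by_concept = {c: train_c.labels(c) for c in CONCEPTS}

    specs = [ModelSpec(family=f, seed=seed) for f in families]
    race_idx = guarded_subsample(Xtr.shape[0], labels_by_concept, race_subsample, folds, seed)
    X_race = Xtr[race_idx].toarray()
    race_labels = {c: labels_by_concept[c][race_idx] for c in CONCEPTS}
    rankings, champion = rank_model_families(specs, X_race, race_labels, folds=folds, seed=seed)

    champ_spec = ModelSpec(family=champion, seed=seed)
    cv_idx = guarded_subsample(Xtr.shape[0], labels_by_concept, cv_subsample, folds, seed + 1)
    X_cv = Xtr[cv_idx].toarray()
    champion_cv = {
        c: cross_validate(champ_spec, X_cv, labels_by_concept[c][cv_idx], folds=folds, seed=seed, concept=c)
        for c in CONCEPTS
    }

    models: dict[Concept, ConceptModel] = {}
    validation_auc: dict[Concept, float] = {}
    validation_auc_ci: dict[Concept, tuple[float, float]] = {}
    diagnostics: dict[Concept, object] = {}
    for c in CONCEPTS:
        model = train(champ_spec, Xtr, labels_by_concept[c], vocab, c)
        p_valid = predict_probability(model, Xva)
        y_valid = valid_c.labels(c)
        model.threshold = youden_threshold(p_valid, y_valid)
        models[c] = model
        validation_auc[c] = roc_auc(p_valid, y_valid)
        validation_auc_ci[c] = bootstrap_auc_ci(
            p_valid, y_valid, replicates=bootstrap_replicates, seed=seed
        )
        diagnostics[c] = binary_diagnostics(p_valid, y_valid, model.threshold)

    return TrainingRun(
        train_corpus=train_c,
        validation_corpus=valid_c,
        vocabulary=vocab,
        rankings=rankings,
        champion_family=champion,
        champion_cv=champion_cv,
        models=models,
        validation_auc=validation_auc,
        validation_auc_ci=validation_auc_ci,
        diagnostics=diagnostics,
    )


def run_grading(
    models: Mapping[Concept, ConceptModel],
    corpus: Corpus,
    k: int = 10,
    ks: Sequence[int] = (5, 10, 15, 20),
    probability_cutoffs: Sequence[float] = (0.60, 0.70, 0.75),
) -> GradingRun:
    """Apply trained concept models to a consultation set and grade quality.

    Produces per-concept agreement at the working ``k``, the K-sensitivity
    table, aggregate capture rates of quantified-risk (grade 3+) sentences
    at each probability cutoff, and the per-concept probability-quality
    regression.
    """
    vocab = next(iter(models.values())).vocabulary
    X = vectorize(corpus.texts(), vocab)
    probabilities = {c: predict_probability(m, X) for c, m in models.items()}

    agreement: dict[Concept, AgreementReport] = {}
    for c, probs in probabilities.items():
        grades = grade_consults(corpus, {c: probs}, k=k)
        agreement[c] = multiclass_agreement(
            [g.actual_score for g in grades], [g.predicted_score for g in grades], concept=c
        )

    ksens = k_sensitivity(corpus, probabilities, ks=ks)

    all_grades = np.concatenate([corpus.grades(c) for c in probabilities])
    all_probs = np.concatenate([probabilities[c] for c in probabilities])
    capture = {cut: capture_rate(all_grades, all_probs, cut) for cut in probability_cutoffs}

    regression = {}
    for c, probs in probabilities.items():
        regression[c] = probability_quality_regression(probs, corpus.grades(c))

    return GradingRun(
        corpus=corpus,
        probabilities=probabilities,
        agreement=agreement,
        k_sensitivity=ksens,
        capture_rates=capture,
        regression=regression,
        k_used=k,
    )
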
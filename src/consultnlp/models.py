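"""Per-concept binary classifiers and model-family comparison.

One independent binary model is trained per concept (nine models total).
Six families are raced by mean ten-fold cross-validated AUC on the
training subset: random forest, decision tree, elastic-net logistic
regression, RBF support vector machine, gradient boosting, and plain
logistic regression.  The family with the best mean rank across concepts
becomes the champion used for validation and for consultation grading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .concepts import Concept
from .evaluation import roc_auc
from .featurize import Vocabulary

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ConceptModel",
    "CvResult",
    "train",
    "predict_probability",
    "cross_validate",
    "rank_model_families",
    "save_bundle",
    "load_bundle",
]

#: Family enumeration order — also the tie-break order in rankings.
FAMILIES = ("random_forest", "decision_tree", "elastic_net", "svm", "gradient_boost", "logistic")


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameters and seed."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")

    def build(self):
        """Instantiate the underlying estimator with recorded settings."""
        params = dict(self.hyperparameters)
        if self.family == "random_forest":
            params.setdefault("n_estimators", 100)
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
        if self.family == "decision_tree":
            return DecisionTreeClassifier(random_state=self.seed, **params)
        if self.family == "elastic_net":
            params.setdefault("l1_ratio", 0.5)
            params.setdefault("C", 1.0)
            params.setdefault("max_iter", 2000)
            return LogisticRegression(solver="saga", random_state=self.seed, **params)
        if self.family == "svm":
            # Platt-scaled probabilities for an RBF SVM, fit on the full
            # training data (ensemble=False mirrors classic SVC scaling)
            svc = SVC(kernel="rbf", random_state=self.seed, **params)
            return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
        if self.family == "gradient_boost":
            params.setdefault("n_estimators", 100)
            return XGBClassifier(
                random_state=self.seed,
                eval_metric="logloss",
                n_jobs=1,
                verbosity=0,
                **params,
            )
        if self.family == "logistic":
            params.setdefault("max_iter", 2000)
            params.setdefault("C", np.inf)
            return LogisticRegression(solver="lbfgs", **params)
        raise AssertionError("unreachable")


@dataclass
class ConceptModel:
    """A fitted classifier for one concept, with its operating threshold."""

    concept: Concept
    spec: ModelSpec
    estimator: object
    vocabulary: Vocabulary
    threshold: float | None = None

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)


@dataclass(frozen=True)
class CvResult:
    """Cross-validated AUC for one (concept, family) pair."""

    concept: Concept
    spec: ModelSpec
    fold_aucs: tuple[float, ...]
    ci_low: float
    ci_high: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def _as_matrix(dtm):
    # dense input is honored as-is: with vocabularies of a few hundred
    # stems, dense fits are several-fold faster than sparse ones
    if sp.issparse(dtm):
        return dtm.tocsr().astype(np.float64)
    return np.asarray(dtm, dtype=np.float64)


def _check_labels(X, labels) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    if y.shape[0] != X.shape[0]:
        raise ValueError("label vector length must equal number of DTM rows")
    if y.all() or (~y).all():
        raise ValueError("degenerate labels: both classes must be present")
    return y


def train(spec: ModelSpec, dtm, labels, vocabulary: Vocabulary, concept: Concept) -> ConceptModel:
    """Fit one family on a document-term matrix; deterministic under spec.seed."""
    X = _as_matrix(dtm)
    y = _check_labels(X, labels)
    est = spec.build()
    est.fit(X, y.astype(int))
    return ConceptModel(concept=concept, spec=spec, estimator=est, vocabulary=vocabulary)


def predict_probability(model: ConceptModel, dtm) -> np.ndarray:
    """Probability of topic concordance per sentence (row)."""
    X = _as_matrix(dtm)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"DTM has {X.shape[1]} columns but model vocabulary has {model.n_features}"
        )
    proba = model.estimator.predict_proba(X)
    classes = list(getattr(model.estimator, "classes_", [0, 1]))
    pos_col = classes.index(1)
    return np.asarray(proba[:, pos_col], dtype=float)


def cross_validate(
    spec: ModelSpec, dtm, labels, folds: int = 10, seed: int = 0, concept: Concept = Concept.TR
) -> CvResult:
    """Stratified k-fold CV; per-fold held-out AUC, mean and normal CI.

    Folds are stratified because at 0.3% prevalence an unstratified fold
    can contain no positives at all.
    """
    X = _as_matrix(dtm)
    y = _check_labels(X, labels)
    n_pos = int(y.sum())
    if n_pos < folds:
        raise ValueError(
            f"only {n_pos} positive sentences for {folds}-fold stratified CV; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    for train_idx, test_idx in skf.split(X, y):
        est = spec.build()
        est.fit(X[train_idx], y[train_idx].astype(int))
        proba = est.predict_proba(X[test_idx])
        pos_col = list(est.classes_).index(1)
        fold_aucs.append(roc_auc(proba[:, pos_col], y[test_idx]))
    arr = np.asarray(fold_aucs)
    se = arr.std(ddof=1) / np.sqrt(folds)
    mean = float(arr.mean())
    return CvResult(
        concept=concept,
        spec=spec,
        fold_aucs=tuple(fold_aucs),
        ci_low=float(np.clip(mean - 1.96 * se, 0.0, 1.0)),
        ci_high=float(np.clip(mean + 1.96 * se, 0.0, 1.0)),
    )


def rank_model_families(
    specs: Sequence[ModelSpec],
    dtm,
    labels_by_concept: Mapping[Concept, Sequence[bool]],
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict[Concept, list[CvResult]], str]:
    """Race model families by mean CV AUC, per concept and overall.

    Returns per-concept rankings (best first) and the overall champion
    family, the one with the best mean rank across concepts.  Ties — both
    within a concept and on mean rank — break by the fixed family
    enumeration order.
    """
    if len(specs) < 1:
        raise ValueError("at least one ModelSpec required")
    rankings: dict[Concept, list[CvResult]] = {}
    rank_sum = {spec.family: 0.0 for spec in specs}
    for concept, labels in labels_by_concept.items():
        results = [cross_validate(spec, dtm, labels, folds=folds, seed=seed, concept=concept) for spec in specs]
        results.sort(key=lambda r: (-r.mean_auc, FAMILIES.index(r.spec.family)))
        rankings[concept] = results
        for rank, r in enumerate(results, start=1):
            rank_sum[r.spec.family] += rank
    champion = min(rank_sum, key=lambda fam: (rank_sum[fam], FAMILIES.index(fam)))
    return rankings, champion


# --- persistence -------------------------------------------------------------


def save_bundle(model: ConceptModel, directory: str | Path) -> None:
    """Save a fitted concept model as a directory bundle.

    Layout: ``spec.json`` (family, hyperparameters, seed, threshold,
    concept), ``vocabulary.txt`` (one stem per line), ``estimator.joblib``
    (library-native serialization), ``manifest.json`` (package versions).
    """
    import sklearn
    import xgboost

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "spec.json").write_text(
        json.dumps(
            {
                "concept": model.concept.value,
                "family": model.spec.family,
                "hyperparameters": dict(model.spec.hyperparameters),
                "seed": model.spec.seed,
                "threshold": model.threshold,
            },
            indent=2,
        )
    )
    model.vocabulary.save(directory / "vocabulary.txt")
    joblib.dump(model.estimator, directory / "estimator.joblib")
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "scikit-learn": sklearn.__version__,
                "xgboost": xgboost.__version__,
                "numpy": np.__version__,
            },
            indent=2,
        )
    )


def load_bundle(directory: str | Path) -> ConceptModel:
    directory = Path(directory)
    meta = json.loads((directory / "spec.json").read_text())
    vocab = Vocabulary.load(directory / "vocabulary.txt")
    estimator = joblib.load(directory / "estimator.joblib")
    spec = ModelSpec(family=meta["family"], hyperparameters=meta["hyperparameters"], seed=meta["seed"])
    return ConceptModel(
        concept=Concept(meta["concept"]),
        spec=spec,
        estimator=estimator,
        vocabulary=vocab,
        threshold=meta["threshold"],
    )
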
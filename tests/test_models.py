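"""Training, probability prediction, cross-validation, family ranking."""

import numpy as np
import pytest

from consultnlp.concepts import Concept
from consultnlp.evaluation import roc_auc
from consultnlp.featurize import Vocabulary
from consultnlp.models import (
    FAMILIES,
    ModelSpec,
    cross_validate,
    load_bundle,
    predict_probability,
    rank_model_families,
    save_bundle,
    train,
)


@pytest.fixture(scope="module")
def separable():
    """Counts where the label is exactly 'keyword present'."""
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(300, 10)).astype(float)
    y = X[:, 0] > 0
    vocab = Vocabulary(stems=tuple(f"stem{i:02d}" for i in range(10)), min_document_frequency=1)
    return X, y, vocab


SMALL_RF = {"n_estimators": 100}


class TestTrain:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_training_auc_is_one(self, separable, family):
        X, y, vocab = separable
        hp = SMALL_RF if family == "random_forest" else {}
        model = train(ModelSpec(family, hp, seed=1), X, y, vocab, Concept.TR)
        assert roc_auc(predict_probability(model, X), y) == pytest.approx(1.0)

    def test_same_seed_identical_probabilities(self, separable):
        X, y, vocab = separable
        spec = ModelSpec("random_forest", SMALL_RF, seed=9)
        p1 = predict_probability(train(spec, X, y, vocab, Concept.TR), X)
        p2 = predict_probability(train(spec, X, y, vocab, Concept.TR), X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, separable):
        X, _, vocab = separable
        with pytest.raises(ValueError, match="degenerate"):
            train(ModelSpec("logistic"), X, np.ones(len(X), bool), vocab, Concept.TR)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("neural_net")


class TestPredict:
    def test_all_zero_row_is_valid_input(self, separable):
        X, y, vocab = separable
        model = train(ModelSpec("logistic", seed=1), X, y, vocab, Concept.TR)
        p = predict_probability(model, np.zeros((1, 10)))
        assert 0.0 <= p[0] <= 1.0

    def test_duplicate_rows_get_identical_probabilities(self, separable):
        X, y, vocab = separable
        model = train(ModelSpec("random_forest", SMALL_RF, seed=1), X, y, vocab, Concept.TR)
        p = predict_probability(model, np.vstack([X[0], X[0]]))
        assert p[0] == p[1]

    def test_column_mismatch_rejected(self, separable):
        X, y, vocab = separable
        model = train(ModelSpec("logistic", seed=1), X, y, vocab, Concept.TR)
        with pytest.raises(ValueError, match="columns"):
            predict_probability(model, X[:, :5])

    def test_invariant_to_column_permutation(self, separable):
        """Refit on permuted columns (with matching vocab) predicts the same."""
        X, y, vocab = separable
        perm = np.random.default_rng(3).permutation(X.shape[1])
        vocab_p = Vocabulary(stems=tuple(vocab.stems[j] for j in perm), min_document_frequency=1)
        m1 = train(ModelSpec("logistic", seed=1), X, y, vocab, Concept.TR)
        m2 = train(ModelSpec("logistic", seed=1), X[:, perm], y, vocab_p, Concept.TR)
        p1 = predict_probability(m1, X)
        p2 = predict_probability(m2, X[:, perm])
        assert np.allclose(p1, p2, atol=1e-6)


class TestCrossValidate:
    def test_separable_all_folds_perfect(self, separable):
        X, y, vocab = separable
        res = cross_validate(ModelSpec("logistic", seed=1), X, y, folds=10, seed=1)
        assert res.fold_aucs == tuple([1.0] * 10)
        assert res.mean_auc == 1.0
        assert res.ci_low <= res.mean_auc <= res.ci_high

    def test_null_labels_auc_near_half(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(2000, 15)).astype(float)
        y = rng.random(2000) < 0.05  # labels independent of features
        res = cross_validate(ModelSpec("logistic", seed=4), X, y, folds=10, seed=4)
        assert 0.4 <= res.mean_auc <= 0.6

    def test_fold_count(self, separable):
        X, y, vocab = separable
        res = cross_validate(ModelSpec("decision_tree", seed=1), X, y, folds=5, seed=1)
        assert len(res.fold_aucs) == 5

    def test_too_few_positives_advises_fewer_folds(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 5))
        y = np.zeros(50, bool)
        y[:4] = True
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ModelSpec("logistic"), X, y, folds=10)

    def test_seeded_reproducibility(self, separable):
        X, y, vocab = separable
        a = cross_validate(ModelSpec("random_forest", SMALL_RF, seed=2), X, y, folds=5, seed=2)
        b = cross_validate(ModelSpec("random_forest", SMALL_RF, seed=2), X, y, folds=5, seed=2)
        assert a.fold_aucs == b.fold_aucs


class TestRanking:
    def test_single_spec_is_champion(self, separable):
        X, y, vocab = separable
        rankings, champion = rank_model_families(
            [ModelSpec("logistic", seed=1)], X, {Concept.TR: y}, folds=5, seed=1
        )
        assert champion == "logistic"
        assert [r.spec.family for r in rankings[Concept.TR]] == ["logistic"]

    def test_tree_ensembles_beat_logistic_on_interaction_signal(self):
        """A parity-of-two-stems rule is invisible to a linear model."""
        rng = np.random.default_rng(11)
        X = rng.integers(0, 2, size=(600, 6)).astype(float)
        y = (X[:, 0] + X[:, 1]) % 2 == 1
        specs = [
            ModelSpec("random_forest", SMALL_RF, seed=11),
            ModelSpec("gradient_boost", seed=11),
            ModelSpec("logistic", seed=11),
        ]
        rankings, champion = rank_model_families(specs, X, {Concept.TR: y}, folds=5, seed=11)
        by_family = {r.spec.family: r.mean_auc for r in rankings[Concept.TR]}
        assert by_family["random_forest"] > by_family["logistic"]
        assert by_family["gradient_boost"] > by_family["logistic"]
        assert champion in ("random_forest", "gradient_boost")

    def test_ranking_reproducible(self, separable):
        X, y, vocab = separable
        specs = [ModelSpec("logistic", seed=5), ModelSpec("decision_tree", seed=5)]
        r1 = rank_model_families(specs, X, {Concept.TR: y}, folds=5, seed=5)
        r2 = rank_model_families(specs, X, {Concept.TR: y}, folds=5, seed=5)
        assert r1[1] == r2[1]
        assert [x.fold_aucs for x in r1[0][Concept.TR]] == [x.fold_aucs for x in r2[0][Concept.TR]]


class TestBundles:
    def test_save_load_round_trip(self, tmp_path, separable):
        X, y, vocab = separable
        model = train(ModelSpec("random_forest", SMALL_RF, seed=1), X, y, vocab, Concept.UI)
        model.threshold = 0.42
        save_bundle(model, tmp_path / "UI")
        back = load_bundle(tmp_path / "UI")
        assert back.concept == Concept.UI
        assert back.threshold == 0.42
        assert back.spec.family == "random_forest"
        assert back.vocabulary.stems == vocab.stems
        assert np.array_equal(predict_probability(back, X), predict_probability(model, X))
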
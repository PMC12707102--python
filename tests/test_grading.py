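"""The top-K consultation grading protocol and its agreement metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consultnlp.concepts import CONCEPTS, Concept
from consultnlp.corpus_io import Corpus
from consultnlp.grading import (
    actual_consult_score,
    capture_rate,
    grade_consults,
    k_sensitivity,
    multiclass_agreement,
    predicted_consult_score,
    probability_quality_regression,
    top_k_indices,
)

from conftest import make_labeled


def consult(grades, concept=Concept.TR, cid="c1"):
    """A one-consult sentence list with the given grades for one concept."""
    return [
        make_labeled(cid, i, f"sentence {i}.", concept if g > 0 else None, g)
        for i, g in enumerate(grades)
    ]


class TestConsultScores:
    def test_never_mentioned_scores_zero(self):
        assert actual_consult_score(consult([0, 0, 0]), Concept.TR) == 0

    def test_max_over_sentences(self):
        assert actual_consult_score(consult([1, 4, 2]), Concept.TR) == 4

    def test_matches_naive_max_oracle(self, rng):
        for _ in range(20):
            grades = rng.integers(0, 6, size=rng.integers(1, 30)).tolist()
            sents = consult(grades)
            assert actual_consult_score(sents, Concept.TR) == max(grades)

    def test_empty_and_mixed_consults_rejected(self):
        with pytest.raises(ValueError):
            actual_consult_score([], Concept.TR)
        mixed = consult([1], cid="a") + consult([2], cid="b")
        with pytest.raises(ValueError, match="multiple"):
            actual_consult_score(mixed, Concept.TR)


class TestTopK:
    def test_largest_first(self):
        assert top_k_indices([0.1, 0.9, 0.5], 2) == [1, 2]

    def test_positional_tie_break(self):
        assert top_k_indices([0.4, 0.4, 0.4], 2) == [0, 1]

    def test_k_exceeding_n_returns_all(self):
        assert top_k_indices([0.3, 0.2, 0.1], 10) == [0, 1, 2]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_k_indices([0.5], 0)


class TestPredictedScore:
    def test_subset_max_can_undergrade(self):
        # the quantified sentence is ranked outside the top-k: the
        # protocol's characteristic error mode
        sents = consult([0, 0, 3])
        probs = [0.9, 0.8, 0.1]
        assert predicted_consult_score(sents, probs, 2, Concept.TR) == 0

    def test_full_coverage_equals_actual(self, rng):
        grades = rng.integers(0, 6, size=15).tolist()
        sents = consult(grades)
        probs = rng.random(15)
        assert predicted_consult_score(sents, probs, 15, Concept.TR) == max(grades)

    def test_matches_subset_max_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            grades = rng.integers(0, 6, size=n).tolist()
            sents = consult(grades)
            probs = rng.random(n)
            k = int(rng.integers(1, 15))
            top = sorted(range(n), key=lambda i: (-probs[i], i))[: min(k, n)]
            assert predicted_consult_score(sents, probs, k, Concept.TR) == max(grades[i] for i in top)

    def test_predicted_never_exceeds_actual(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 25))
            grades = rng.integers(0, 6, size=n).tolist()
            sents = consult(grades)
            probs = rng.random(n)
            k = int(rng.integers(1, 30))
            assert predicted_consult_score(sents, probs, k, Concept.TR) <= max(grades)


class TestAgreement:
    # printed agreement rows: n correct of 20 -> the six metrics
    @pytest.mark.parametrize(
        "n_correct,expected",
        [
            (20, (1.00, 1.00, 1.00, 1.00, 1.00, 1.00)),
            (19, (0.95, 0.97, 0.95, 0.99, 0.95, 0.99)),
            (18, (0.90, 0.94, 0.90, 0.98, 0.90, 0.98)),
            (17, (0.85, 0.91, 0.85, 0.97, 0.85, 0.97)),
            (16, (0.80, 0.88, 0.80, 0.96, 0.80, 0.96)),
        ],
    )
    def test_micro_metrics_reproduce_reference_rows(self, n_correct, expected):
        actual = [i % 6 for i in range(20)]
        predicted = [a if i < n_correct else (a + 1) % 6 for i, a in enumerate(actual)]
        rep = multiclass_agreement(actual, predicted)
        got = (rep.accuracy, rep.balanced_accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv)
        assert tuple(round(x, 2) for x in got) == expected

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_micro_identities_hold_for_any_input(self, pairs):
        actual = [a for a, _ in pairs]
        predicted = [p for _, p in pairs]
        rep = multiclass_agreement(actual, predicted)
        assert rep.confusion.sum() == len(pairs)
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / len(pairs))
        assert rep.sensitivity == pytest.approx(rep.accuracy)
        assert rep.ppv == pytest.approx(rep.accuracy)
        assert rep.specificity == pytest.approx(1 - (1 - rep.accuracy) / 5)
        assert rep.npv == pytest.approx(rep.specificity)
        assert rep.balanced_accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)

    def test_errors(self):
        with pytest.raises(ValueError):
            multiclass_agreement([1, 2], [1])
        with pytest.raises(ValueError):
            multiclass_agreement([6], [0])


def two_consult_corpus(rng, n=30):
    sents = []
    for cid in ("c1", "c2"):
        grades = rng.integers(0, 6, size=n).tolist()
        sents.extend(consult(grades, cid=cid))
    return Corpus(sentences=sents)


class TestKSensitivity:
    def test_accuracy_non_decreasing_in_k(self, rng):
        for _ in range(5):
            corpus = two_consult_corpus(rng)
            probs = {Concept.TR: rng.random(len(corpus))}
            res = k_sensitivity(corpus, probs, ks=(2, 5, 10, 30))
            accs = res.accuracy[Concept.TR]
            assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))

    def test_full_coverage_k_reaches_perfect_accuracy(self, rng):
        corpus = two_consult_corpus(rng, n=12)
        probs = {Concept.TR: rng.random(len(corpus))}
        res = k_sensitivity(corpus, probs, ks=(12,))
        assert res.accuracy[Concept.TR] == (1.0,)

    def test_single_consult_accuracy_is_zero_or_one(self, rng):
        corpus = Corpus(sentences=consult(rng.integers(0, 6, size=20).tolist()))
        probs = {Concept.TR: rng.random(20)}
        res = k_sensitivity(corpus, probs, ks=(3,))
        assert res.accuracy[Concept.TR][0] in (0.0, 1.0)

    def test_grade_consults_invariant(self, small_corpus, rng):
        probs = {c: rng.random(len(small_corpus)) for c in CONCEPTS}
        for g in grade_consults(small_corpus, probs, k=10):
            assert g.predicted_score <= g.actual_score


class TestCaptureRate:
    def test_no_qualifying_sentence_is_unset(self):
        assert capture_rate([0, 1, 2], [0.9, 0.9, 0.9], 0.6) is None

    def test_all_captured(self):
        assert capture_rate([3, 4, 5], [0.9, 0.9, 0.9], 0.6) == 1.0

    def test_strict_inequality_at_cutoff(self):
        assert capture_rate([3], [0.6], 0.6) == 0.0

    def test_monotone_non_increasing_in_cutoff(self, rng):
        grades = rng.integers(0, 6, size=300)
        probs = rng.random(300)
        rates = [capture_rate(grades, probs, c) for c in (0.60, 0.70, 0.75)]
        assert rates[0] >= rates[1] >= rates[2]


class TestRegression:
    def test_noiseless_fit_recovers_slope(self):
        probs = np.linspace(0.1, 0.9, 30)
        grades = 2.0 + 3.0 * probs
        slope, intercept, p = probability_quality_regression(probs, grades)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(2.0)
        assert p < 1e-12

    def test_null_association_rarely_significant(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            probs = rng.random(500)
            grades = rng.integers(0, 6, size=500)
            _, _, p = probability_quality_regression(probs, grades)
            hits += p > 0.05
        assert hits >= 45  # slope CI covers zero in >= 90% of trials

    def test_planted_association_detected(self, small_corpus):
        # probability tracks grade by construction
        rng = np.random.default_rng(0)
        grades = small_corpus.grades(Concept.PR)
        probs = np.clip(0.15 * grades + 0.1 * rng.random(len(grades)), 0, 1)
        slope, _, p = probability_quality_regression(probs, grades)
        assert slope > 0 and p < 0.05

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            probability_quality_regression([0.5, 0.5, 0.5], [1, 2, 3])
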
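import numpy as np
import pytest

from consultnlp.concepts import CONCEPTS, Concept
from consultnlp.corpus_io import Corpus, LabeledSentence, Sentence, Speaker
from consultnlp.synthgen import DEFAULT_PREVALENCE, GeneratorConfig, generate_corpus


def make_labeled(
    consult_id: str,
    index: int,
    text: str,
    concept: Concept | None = None,
    grade: int = 0,
    speaker: Speaker = Speaker.PHYSICIAN,
) -> LabeledSentence:
    """Build a LabeledSentence with at most one positive concept."""
    labels = {c: False for c in CONCEPTS}
    grades = {c: 0 for c in CONCEPTS}
    if concept is not None:
        labels[concept] = True
        grades[concept] = grade
    return LabeledSentence(
        sentence=Sentence(consult_id=consult_id, index=index, speaker=speaker, text=text),
        labels=labels,
        grades=grades,
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down generator: 8 consultations of ~120 sentences with
    prevalences four times the development corpus, so every concept has
    enough positives for unit-level checks."""
    return GeneratorConfig(
        n_consults=8,
        sentences_per_consult=(120.0, 10.0),
        prevalence={c: 4 * p for c, p in DEFAULT_PREVALENCE.items()},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config) -> Corpus:
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
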
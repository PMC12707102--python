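"""Synthetic labeled consultation corpora.

Real consultation transcripts are private clinical recordings, so every
pipeline stage is exercised on generated corpora that reproduce the
development dataset's statistical shape: 50 consultations averaging about
579 sentences each (roughly 28,900 in total), sentence-level concept
prevalences between 0.3% and 2.4%, and grade-dependent quantification
language so that sentences communicating more detailed risk score higher
with the classifiers.

The generator produces token-salad text, not grammatical English: each
sentence is a bag of filler words, plus concept keywords and (for grades
of 3 and above) quantification phrases when the sentence is topical.
Keyword lexicons are invented fixtures chosen for face validity; they are
not measured from any real corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .concepts import CONCEPTS, Concept
from .corpus_io import Corpus, LabeledSentence, Sentence, Speaker
from .featurize import preprocess_text

__all__ = ["GeneratorConfig", "default_config", "generate_corpus", "generate_validation_set"]

#: Development-corpus sentence prevalences (fraction of all sentences
#: labeled positive), in canonical concept order: 1.2, 2.4, 0.4, 1.2,
#: 0.3, 0.3, 2.1, 1.2, 1.0 percent.
DEFAULT_PREVALENCE: dict[Concept, float] = {
    Concept.TR: 0.012,
    Concept.PR: 0.024,
    Concept.LE: 0.004,
    Concept.CP: 0.012,
    Concept.UF: 0.003,
    Concept.EF: 0.003,
    Concept.ED: 0.021,
    Concept.UI: 0.012,
    Concept.LUTS: 0.010,
}

# Invented keyword lexicons, one per concept, stem-disjoint by design.
DEFAULT_LEXICONS: dict[Concept, tuple[str, ...]] = {
    Concept.TR: ("risk", "intermediate", "favorable", "unfavorable", "aggressive"),
    Concept.PR: ("biopsy", "cores", "gleason", "pathology", "specimen"),
    Concept.LE: ("expectancy", "longevity", "actuarial", "lifespan", "comorbidity"),
    Concept.CP: ("prognosis", "survival", "cure", "recurrence", "metastasis"),
    Concept.UF: ("stream", "voiding", "emptying", "uroflow", "retention"),
    Concept.EF: ("erections", "firmness", "libido", "potency", "intimacy"),
    Concept.ED: ("dysfunction", "impotence", "viagra", "cialis", "rigidity"),
    Concept.UI: ("incontinence", "leakage", "pads", "dribbling", "sphincter"),
    Concept.LUTS: ("urgency", "frequency", "burning", "irritative", "nocturia"),
}

#: Quantification phrases attached to grade-3+ sentences (number words
#: that survive stop-word removal, plus risk-quantity vocabulary).
QUANTIFICATION_WORDS: tuple[str, ...] = (
    "percent", "percentage", "chance", "odds", "likelihood",
    "probability", "estimate", "roughly", "approximately", "quantified",
)

#: Patient-specific framing attached to grade-5 sentences.
PERSONALIZED_WORDS: tuple[str, ...] = ("individualized", "tailored", "personalized", "specific")

FILLER_VOCABULARY: tuple[str, ...] = (
    "treatment", "options", "surgery", "radiation", "therapy", "doctor",
    "patient", "question", "discuss", "today", "appointment", "results",
    "scan", "imaging", "prostate", "cancer", "cells", "body", "health",
    "feel", "talk", "important", "decision", "information", "nurse",
    "office", "schedule", "follow", "visit", "week", "month", "time",
    "good", "right", "little", "team", "plan", "review", "look",
    "consider", "understand", "different", "approach", "monitor",
    "active", "surveillance", "check", "blood", "test", "psa", "level",
    "normal", "report", "letter", "family", "support", "home", "work",
    "drive", "walk", "exercise", "diet", "sleep", "energy", "medicine",
    "dose", "pill", "clinic", "phone", "call", "message", "insurance",
    "referral", "morning", "afternoon", "hospital", "procedure", "gland",
    "tissue", "recovery", "healing", "weeks", "studies", "research",
)

#: Probability that a topical sentence carries grade g in {1..5}; most
#: topical mentions are unquantified, mirroring how often quantified risk
#: communication is absent from real consultations.
DEFAULT_GRADE_DISTRIBUTION: dict[int, float] = {1: 0.35, 2: 0.25, 3: 0.20, 4: 0.12, 5: 0.08}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic corpus generator.

    ``sentences_per_consult`` is (mean, dispersion) of a negative-binomial
    count, so consultation lengths vary realistically around the mean.
    ``noise_rate`` is the fraction of topical sentences rendered *without*
    their lexicon — label noise in the features, which keeps classifiers
    imperfect the way real paraphrased clinical language does.
    """

    n_consults: int = 50
    sentences_per_consult: tuple[float, float] = (578.54, 25.0)  # 28,927 / 50 consults
    prevalence: Mapping[Concept, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    lexicons: Mapping[Concept, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_LEXICONS))
    grade_distribution: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_GRADE_DISTRIBUTION))
    filler_vocabulary: tuple[str, ...] = FILLER_VOCABULARY
    quantification_words: tuple[str, ...] = QUANTIFICATION_WORDS
    personalized_words: tuple[str, ...] = PERSONALIZED_WORDS
    noise_rate: float = 0.05
    allow_multi_concept: bool = False
    seed: int = 20190101

    def __post_init__(self) -> None:
        prev = {Concept(c): float(p) for c, p in self.prevalence.items()}
        if set(prev) != set(CONCEPTS):
            raise ValueError("prevalence must configure all 9 concepts")
        if any(not 0 <= p < 1 for p in prev.values()) or sum(prev.values()) >= 1:
            raise ValueError("prevalences must lie in [0, 1) and leave room for filler")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must lie in [0, 1)")
        gd = {int(g): float(w) for g, w in self.grade_distribution.items()}
        if set(gd) != {1, 2, 3, 4, 5} or abs(sum(gd.values()) - 1.0) > 1e-9:
            raise ValueError("grade_distribution must weight levels 1..5 and sum to 1")
        object.__setattr__(self, "prevalence", prev)
        object.__setattr__(self, "grade_distribution", gd)
        object.__setattr__(self, "lexicons", {Concept(c): tuple(v) for c, v in self.lexicons.items()})

    def lexicon_stems(self, concept: Concept) -> set[str]:
        """Stems of the planted keywords (as the featurizer will see them)."""
        stems: set[str] = set()
        for word in self.lexicons[concept]:
            stems.update(preprocess_text(word))
        return stems


def default_config(seed: int = 20190101) -> GeneratorConfig:
    """The study conditions: 50 consultations, ~579 sentences each."""
    return GeneratorConfig(seed=seed)


def _sentence_text(
    concept: Concept | None,
    grade: int,
    noisy: bool,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> str:
    n_filler = int(rng.integers(4, 12))
    words = list(rng.choice(config.filler_vocabulary, size=n_filler))
    if concept is not None and not noisy:
        lexicon = config.lexicons[concept]
        n_keywords = 1 + (grade >= 2) + (grade >= 4)
        words.extend(rng.choice(lexicon, size=n_keywords))
        if grade >= 3:
            n_quant = grade - 1
            words.extend(rng.choice(config.quantification_words, size=n_quant))
        if grade >= 5:
            words.extend(rng.choice(config.personalized_words, size=2))
    rng.shuffle(words)
    return " ".join(words) + "."


def _generate(
    config: GeneratorConfig,
    n_consults: int,
    mean_sentences: float,
    id_prefix: str,
    seed_seq: np.random.SeedSequence,
) -> Corpus:
    structure_ss, lexicon_ss, noise_ss = seed_seq.spawn(3)
    structure = np.random.default_rng(structure_ss)
    lexicon_rng = np.random.default_rng(lexicon_ss)
    noise_rng = np.random.default_rng(noise_ss)

    concepts = list(CONCEPTS)
    prev = np.array([config.prevalence[c] for c in concepts])
    p_filler = 1.0 - prev.sum()
    choice_p = np.concatenate([prev, [p_filler]])
    grades_levels = np.array(sorted(config.grade_distribution))
    grades_p = np.array([config.grade_distribution[g] for g in grades_levels])
    mean, dispersion = mean_sentences, config.sentences_per_consult[1]
    nb_p = dispersion / (dispersion + mean)

    sentences: list[LabeledSentence] = []
    for c in range(n_consults):
        cid = f"{id_prefix}{c + 1:03d}"
        n = max(int(structure.negative_binomial(dispersion, nb_p)), 20)
        draws = structure.choice(len(concepts) + 1, size=n, p=choice_p)
        for i in range(n):
            labels = {cc: False for cc in concepts}
            grades = {cc: 0 for cc in concepts}
            primary: Concept | None = None
            grade = 0
            if draws[i] < len(concepts):
                primary = concepts[draws[i]]
                grade = int(structure.choice(grades_levels, p=grades_p))
                labels[primary] = True
                grades[primary] = grade
            if config.allow_multi_concept and primary is not None:
                for j, cc in enumerate(concepts):
                    if cc is not primary and structure.random() < prev[j]:
                        labels[cc] = True
                        grades[cc] = int(structure.choice(grades_levels, p=grades_p))
            noisy = primary is not None and noise_rng.random() < config.noise_rate
            text = _sentence_text(primary, grade, noisy, config, lexicon_rng)
            sentences.append(
                LabeledSentence(
                    sentence=Sentence(consult_id=cid, index=i, speaker=Speaker.PHYSICIAN, text=text),
                    labels=labels,
                    grades=grades,
                )
            )
    return Corpus(sentences=sentences)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a development-style corpus; byte-reproducible under seed."""
    return _generate(
        config,
        n_consults=config.n_consults,
        mean_sentences=config.sentences_per_consult[0],
        id_prefix="T",
        seed_seq=np.random.SeedSequence(config.seed),
    )


def generate_validation_set(
    config: GeneratorConfig, n_consults: int = 20, mean_sentences: float | None = None
) -> Corpus:
    """An independent quality-evaluation corpus.

    Sized like the 20-consultation validation set (about 468 sentences per
    consultation, roughly 9,400 in total), drawn from a fresh seed stream
    so it shares no randomness with the development corpus, with disjoint
    consult identifiers.
    """
    return _generate(
        config,
        n_consults=n_consults,
        mean_sentences=468.35 if mean_sentences is None else mean_sentences,  # 9,367 / 20
        id_prefix="V",
        seed_seq=np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)),
    )
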
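"""Stemmed bag-of-words features for consultation sentences.

Pipeline: lowercase, strip punctuation and digits-only tokens, tokenize on
whitespace, drop stop words, Snowball-stem.  Sentences are short, so raw
stem counts are the default representation (TF-IDF is available as an
option); unigrams only unless an n-gram range is requested.  The
vocabulary is always built on training sentences only, so the internal
validation subset never leaks into feature selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from .stemming import stem
from .stopwords import STOP_WORDS

__all__ = [
    "preprocess_text",
    "Vocabulary",
    "build_vocabulary",
    "vectorize",
    "variable_importance",
]

_TOKEN_CLEAN_RE = re.compile(r"[^a-z0-9']+")
_DIGITS_ONLY_RE = re.compile(r"^[0-9]+$")


def preprocess_text(text: str, ngram_range: tuple[int, int] = (1, 1)) -> list[str]:
    """Tokenize a sentence into stem tokens (optionally n-grams of stems)."""
    tokens: list[str] = []
    for raw in text.lower().split():
        token = _TOKEN_CLEAN_RE.sub(" ", raw)
        for part in token.split():
            part = part.strip("'")
            if not part or _DIGITS_ONLY_RE.match(part):
                continue
            if part in STOP_WORDS:
                continue
            tokens.append(stem(part))
    lo, hi = ngram_range
    if (lo, hi) == (1, 1):
        return tokens
    grams: list[str] = []
    for n in range(lo, hi + 1):
        grams.extend(" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
    return grams


@dataclass(frozen=True)
class Vocabulary:
    """An ordered, duplicate-free stem list fit on training sentences."""

    stems: tuple[str, ...]
    min_document_frequency: int = 2
    ngram_range: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if len(set(self.stems)) != len(self.stems):
            raise ValueError("vocabulary contains duplicate stems")

    def __len__(self) -> int:
        return len(self.stems)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.stems)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.stems) + "\n")

    @classmethod
    def load(cls, path: str | Path, min_document_frequency: int = 2) -> "Vocabulary":
        stems = tuple(line for line in Path(path).read_text().splitlines() if line)
        return cls(stems=stems, min_document_frequency=min_document_frequency)


def build_vocabulary(
    train_texts: Sequence[str],
    min_document_frequency: int = 2,
    ngram_range: tuple[int, int] = (1, 1),
) -> Vocabulary:
    """Stems occurring in at least ``min_document_frequency`` distinct
    training sentences, sorted lexicographically for determinism."""
    if min_document_frequency < 1:
        raise ValueError("min_document_frequency must be >= 1")
    if not train_texts:
        raise ValueError("cannot build a vocabulary from zero sentences")
    df: dict[str, int] = {}
    for text in train_texts:
        for token in set(preprocess_text(text, ngram_range)):
            df[token] = df.get(token, 0) + 1
    stems = tuple(sorted(t for t, n in df.items() if n >= min_document_frequency))
    return Vocabulary(stems=stems, min_document_frequency=min_document_frequency, ngram_range=ngram_range)


def vectorize(texts: Sequence[str], vocab: Vocabulary, tfidf: bool = False) -> sp.csr_matrix:
    """Sparse document-term matrix of in-vocabulary stem counts.

    Out-of-vocabulary stems are ignored, which is what lets a trained
    model score sentences from consultations it has never seen.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    index = vocab.index
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for text in texts:
        counts: dict[int, int] = {}
        for token in preprocess_text(text, vocab.ngram_range):
            j = index.get(token)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        indices.extend(counts.keys())
        data.extend(counts.values())
        indptr.append(len(indices))
    dtm = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), np.asarray(indices, dtype=np.int32), np.asarray(indptr, dtype=np.int32)),
        shape=(len(texts), len(vocab)),
    )
    dtm.sort_indices()
    if tfidf:
        dtm = TfidfTransformer().fit_transform(dtm).tocsr()
    return dtm


def save_dtm(dtm: sp.csr_matrix, path: str | Path) -> None:
    """Write a DTM in Matrix Market format (text, exchangeable)."""
    scipy.io.mmwrite(str(path), dtm)


def variable_importance(model, vocab: Vocabulary, top_n: int = 5) -> list[tuple[str, float]]:
    """Top stems by model importance, ties broken lexicographically.

    Tree ensembles expose impurity importances; linear families use the
    absolute coefficient.  Families without a notion of importance (RBF
    support vector machines) raise.
    """
    est = getattr(model, "estimator", model)
    if hasattr(est, "feature_importances_"):
        scores = np.asarray(est.feature_importances_, dtype=float)
    elif hasattr(est, "coef_"):
        scores = np.abs(np.asarray(est.coef_, dtype=float)).ravel()
    else:
        raise TypeError(f"model family {type(est).__name__} does not expose variable importances")
    if len(scores) != len(vocab):
        raise ValueError(f"model has {len(scores)} features but vocabulary has {len(vocab)}")
    if top_n <= 0:
        return []
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], vocab.stems[j]))
    return [(vocab.stems[j], float(scores[j])) for j in order[:top_n]]
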
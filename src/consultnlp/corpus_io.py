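"""Reading, writing, segmenting, and splitting consultation corpora.

A corpus is an ordered collection of sentences, each carrying a consult
identifier, its 0-based position within the consultation, a speaker tag,
nine binary topic labels and nine ordinal 0-5 quality grades.  JSONL (one
record per sentence) is the canonical on-disk schema; CSV with one column
per label (``label_TR`` ...) and grade (``grade_TR`` ...) is supported for
spreadsheet interoperability.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .concepts import CONCEPTS, Concept

__all__ = [
    "Speaker",
    "Sentence",
    "LabeledSentence",
    "Corpus",
    "SchemaError",
    "segment_transcript",
    "read_corpus",
    "write_corpus",
    "split_corpus",
]


class SchemaError(ValueError):
    """A record violates the corpus schema or a type invariant."""


class Speaker(str, Enum):
    PHYSICIAN = "physician"
    PATIENT = "patient"
    OTHER = "other"


@dataclass(frozen=True)
class Sentence:
    """One transcript sentence.

    ``index`` is the 0-based position within the consultation; ``text`` is
    stored stripped of surrounding whitespace and must be non-empty.
    """

    consult_id: str
    index: int
    speaker: Speaker
    text: str

    def __post_init__(self) -> None:
        stripped = self.text.strip()
        if not stripped:
            raise SchemaError(f"empty sentence text (consult {self.consult_id}, index {self.index})")
        object.__setattr__(self, "text", stripped)
        object.__setattr__(self, "speaker", Speaker(self.speaker))
        if self.index < 0:
            raise SchemaError(f"negative sentence index {self.index}")


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence plus its nine binary topic labels and 0-5 quality grades.

    Invariants: a positive grade implies the label is set, an unset label
    implies grade 0, and all nine concepts are present in both maps.
    """

    sentence: Sentence
    labels: Mapping[Concept, bool]
    grades: Mapping[Concept, int]

    def __post_init__(self) -> None:
        labels = {Concept(c): bool(v) for c, v in self.labels.items()}
        grades = {Concept(c): int(v) for c, v in self.grades.items()}
        missing = [c.value for c in CONCEPTS if c not in labels or c not in grades]
        if missing:
            raise SchemaError(f"missing concepts {missing} (consult {self.sentence.consult_id}, index {self.sentence.index})")
        for c in CONCEPTS:
            g = grades[c]
            if not 0 <= g <= 5:
                raise SchemaError(f"grade {g} for {c.value} outside [0, 5] (consult {self.sentence.consult_id}, index {self.sentence.index})")
            if g > 0 and not labels[c]:
                raise SchemaError(
                    f"grade {g} for {c.value} but label unset (consult {self.sentence.consult_id}, index {self.sentence.index})"
                )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "grades", grades)


@dataclass
class Corpus:
    """An ordered, non-empty collection of labeled sentences."""

    sentences: list[LabeledSentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sentences:
            raise SchemaError("corpus must contain at least one sentence")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[LabeledSentence]:
        return iter(self.sentences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.sentences == other.sentences

    @property
    def consult_ids(self) -> list[str]:
        """Distinct consult identifiers, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sentences:
            seen.setdefault(s.sentence.consult_id, None)
        return list(seen)

    def texts(self) -> list[str]:
        return [s.sentence.text for s in self.sentences]

    def labels(self, concept: Concept) -> np.ndarray:
        """Boolean label vector for one concept, aligned to sentence order."""
        return np.array([s.labels[concept] for s in self.sentences], dtype=bool)

    def grades(self, concept: Concept) -> np.ndarray:
        return np.array([s.grades[concept] for s in self.sentences], dtype=int)

    def prevalence(self, concept: Concept) -> float:
        """Fraction of sentences labeled positive for ``concept``."""
        return float(self.labels(concept).mean())

    def by_consult(self) -> dict[str, list[LabeledSentence]]:
        """Sentences grouped by consultation, preserving order."""
        groups: dict[str, list[LabeledSentence]] = {}
        for s in self.sentences:
            groups.setdefault(s.sentence.consult_id, []).append(s)
        return groups

    def validate_indices(self) -> None:
        """Check that per-consult indices are contiguous from 0."""
        for cid, group in self.by_consult().items():
            indices = sorted(s.sentence.index for s in group)
            if indices != list(range(len(group))):
                raise SchemaError(f"consult {cid}: sentence indices not contiguous from 0")


# --- transcript segmentation -------------------------------------------------

#: Abbreviations whose trailing period does not end a sentence.
ABBREVIATIONS = ("Dr.", "Mr.", "Mrs.", "Ms.", "St.", "vs.", "e.g.", "i.e.", "No.", "etc.", "Prof.")

# Candidate boundaries: . ! ? followed by whitespace or end of line.  A
# period that terminates a guarded abbreviation is not a boundary.
_TERMINAL_RE = re.compile(r"[.!?](?=\s|$)")
_ABBREV_LOWER = {a.lower() for a in ABBREVIATIONS}


def _split_sentences(text: str) -> list[str]:
    parts: list[str] = []
    start = 0
    for m in _TERMINAL_RE.finditer(text):
        end = m.end()
        chunk = text[start:end].strip()
        last_token = chunk.rsplit(None, 1)[-1] if chunk else ""
        if m.group() == "." and last_token.lower() in _ABBREV_LOWER:
            continue
        if chunk:
            parts.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        parts.append(tail)
    return parts


def segment_transcript(
    raw_text: str,
    consult_id: str,
    speaker_markers: Mapping[str, Speaker | str] | None = None,
) -> list[Sentence]:
    """Segment a raw transcript into sentences.

    Lines may begin with a speaker marker (for example ``"DR:"`` mapped to
    ``Speaker.PHYSICIAN``); unmarked lines default to the physician, the
    party whose quotes are coded.  Boundaries are placed at terminal
    punctuation with a fixed abbreviation guard; no statistical splitter is
    used, so segmentation is bit-reproducible.
    """
    markers = {k: Speaker(v) for k, v in (speaker_markers or {}).items()}
    sentences: list[Sentence] = []
    index = 0
    for line in raw_text.splitlines():
        line = line.strip()
        if not line:
            continue
        speaker = Speaker.PHYSICIAN
        for prefix, spk in markers.items():
            if line.startswith(prefix):
                speaker = spk
                line = line[len(prefix):].strip()
                break
        for text in _split_sentences(line):
            sentences.append(Sentence(consult_id=consult_id, index=index, speaker=speaker, text=text))
            index += 1
    return sentences


# --- serialization -----------------------------------------------------------


def _record_to_sentence(record: Mapping, recno: int, code_speakers: tuple[str, ...] | None) -> LabeledSentence:
    try:
        sent = Sentence(
            consult_id=str(record["consult_id"]),
            index=int(record["index"]),
            speaker=Speaker(record["speaker"]),
            text=str(record["text"]),
        )
        labels = {Concept(k): bool(v) for k, v in record["labels"].items()}
        grades = {Concept(k): int(v) for k, v in record["grades"].items()}
        ls = LabeledSentence(sentence=sent, labels=labels, grades=grades)
    except (KeyError, ValueError, TypeError) as exc:
        raise SchemaError(f"record {recno}: {exc}") from exc
    if code_speakers is not None and ls.sentence.speaker.value not in code_speakers:
        if any(ls.labels.values()):
            raise SchemaError(
                f"record {recno}: labels set on {ls.sentence.speaker.value} sentence "
                f"(only {code_speakers} sentences are coded; pass code_speakers=None to allow)"
            )
    return ls


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    code_speakers: tuple[str, ...] | None = ("physician",),
) -> Corpus:
    """Read a labeled corpus from JSONL or CSV.

    By default only physician sentences may carry labels, mirroring coding
    of physician quotes; pass ``code_speakers=None`` to accept labels on
    any speaker.
    """
    path = Path(path)
    if format == "jsonl":
        records: list[dict] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"record {lineno}: invalid JSON ({exc})") from exc
    elif format == "csv":
        frame = pd.read_csv(path, dtype={"consult_id": str})
        records = []
        for row in frame.to_dict(orient="records"):
            records.append(
                {
                    "consult_id": row["consult_id"],
                    "index": row["index"],
                    "speaker": row["speaker"],
                    "text": row["text"],
                    "labels": {c.value: bool(row[f"label_{c.value}"]) for c in CONCEPTS},
                    "grades": {c.value: int(row[f"grade_{c.value}"]) for c in CONCEPTS},
                }
            )
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
    sentences = [_record_to_sentence(rec, i + 1, code_speakers) for i, rec in enumerate(records)]
    return Corpus(sentences=sentences)


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus so that :func:`read_corpus` reproduces it exactly."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w") as fh:
            for s in corpus:
                record = {
                    "consult_id": s.sentence.consult_id,
                    "index": s.sentence.index,
                    "speaker": s.sentence.speaker.value,
                    "text": s.sentence.text,
                    "labels": {c.value: s.labels[c] for c in CONCEPTS},
                    "grades": {c.value: s.grades[c] for c in CONCEPTS},
                }
                fh.write(json.dumps(record) + "\n")
    elif format == "csv":
        rows = []
        for s in corpus:
            row: dict = {
                "consult_id": s.sentence.consult_id,
                "index": s.sentence.index,
                "speaker": s.sentence.speaker.value,
                "text": s.sentence.text,
            }
            for c in CONCEPTS:
                row[f"label_{c.value}"] = int(s.labels[c])
            for c in CONCEPTS:
                row[f"grade_{c.value}"] = s.grades[c]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")


def split_corpus(
    corpus: Corpus,
    train_fraction: float = 0.75,
    seed: int = 0,
    by_consult: bool = False,
) -> tuple[Corpus, Corpus]:
    """Random train/validation split.

    The default splits at the *sentence* level, uniformly at random, with
    training size ``floor(train_fraction * N)`` — on 28,927 sentences at
    0.75 this yields the 21,695 / 7,232 partition.  Sentence-level
    splitting lets sentences from one consultation land in both parts;
    ``by_consult=True`` instead assigns whole consultations to one side
    (training size = floor of the consult count).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(corpus) < 2:
        raise ValueError("need at least 2 sentences to split")
    rng = np.random.default_rng(seed)
    if by_consult:
        ids = corpus.consult_ids
        if len(ids) < 2:
            raise ValueError("need at least 2 consultations for a consult-level split")
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(train_fraction * len(ids)))
        train_ids = {ids[i] for i in perm[:n_train]}
        train = [s for s in corpus if s.sentence.consult_id in train_ids]
        valid = [s for s in corpus if s.sentence.consult_id not in train_ids]
    else:
        n = len(corpus)
        perm = rng.permutation(n)
        n_train = int(np.floor(train_fraction * n))
        train_idx = np.sort(perm[:n_train])
        valid_idx = np.sort(perm[n_train:])
        train = [corpus.sentences[i] for i in train_idx]
        valid = [corpus.sentences[i] for i in valid_idx]
    if not train or not valid:
        raise ValueError("split produced an empty part; adjust train_fraction")
    return Corpus(sentences=train), Corpus(sentences=valid)
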
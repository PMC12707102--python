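"""Segment a raw transcript into sentences and build a labeled corpus.

Transcripts arrive as plain text with optional speaker markers; sentences
are the unit of coding, so everything downstream works on a
sentence-per-record corpus.
"""

from consultnlp import Concept, segment_transcript
from consultnlp.corpus_io import Corpus, LabeledSentence
from consultnlp.concepts import CONCEPTS

TRANSCRIPT = """\
DR: Good morning. I reviewed the biopsy with Dr. Lee.
DR: The Gleason score puts you in the intermediate risk group.
DR: After surgery, roughly twenty percent of men have some leakage at one year.
PT: That is a lot to take in.
"""

sentences = segment_transcript(TRANSCRIPT, "consult-001", {"DR:": "physician", "PT:": "patient"})
print(f"{len(sentences)} sentences:")
for s in sentences:
    print(f"  [{s.index}] ({s.speaker.value}) {s.text}")

# Coding attaches 9 binary topic labels and 0-5 quality grades per sentence.
# Sentence 2 quantifies a side-effect risk: urinary incontinence, grade 3+.
labels = {c: False for c in CONCEPTS}
grades = {c: 0 for c in CONCEPTS}
labels[Concept.UI] = True
grades[Concept.UI] = 4
coded = LabeledSentence(sentence=sentences[3 - 1], labels=labels, grades=grades)
corpus = Corpus(sentences=[coded])
print("\nCoded one sentence:", {c.value: g for c, g in coded.grades.items() if g})
print("A grade of 3+ means the risk was quantified, not merely mentioned.")
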
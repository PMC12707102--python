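"""Generate a synthetic consultation corpus and inspect its statistics.

Real consultation recordings are private, so the generator emulates the
development dataset's shape: consultation lengths, per-concept sentence
prevalences around 0.3-2.4%, and quantification language on grade-3+
sentences.  Scaled down here to keep the example quick.
"""

from consultnlp import CONCEPTS
from consultnlp.synthgen import GeneratorConfig, generate_corpus

config = GeneratorConfig(n_consults=10, sentences_per_consult=(200, 20), seed=42)
corpus = generate_corpus(config)

print(f"{len(corpus)} sentences across {len(corpus.consult_ids)} consultations\n")
print("concept  configured  realized   positives")
for c in CONCEPTS:
    realized = corpus.prevalence(c)
    n_pos = int(corpus.labels(c).sum())
    print(f"{c.value:7s}  {config.prevalence[c]:9.1%}  {realized:8.1%}   {n_pos:6d}")

example = next(s for s in corpus if s.grades[CONCEPTS[0]] >= 3)
print("\nA grade-3+ sentence (quantification language planted):")
print(" ", example.sentence.text)
print("Realized prevalences fluctuate binomially around the configured rates.")
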
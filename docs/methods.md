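# Methods

`consultnlp` measures the quality of physician risk communication in
treatment consultations for newly diagnosed, clinically localized
prostate cancer. It implements a two-stage procedure: sentence-level
topic classification for nine shared-decision-making (SDM) concepts, and
consultation-level quality grading by top-K sentence extraction.

## Problem and data model

AUA guidelines ask consultations to cover five content areas, decomposed
here into nine binary sentence-level concepts: tumor risk (TR),
pathology results (PR), life expectancy (LE), cancer prognosis (CP),
baseline urinary and erectile function (UF, EF), and the side effects
erectile dysfunction (ED), urinary incontinence (UI), and irritative
lower urinary tract symptoms (LUTS).

A corpus is an ordered set of sentences, each with a consultation id, a
0-based position, a speaker tag, nine binary topic labels, and nine
ordinal quality grades on a 0–5 hierarchy: 0 = not mentioned, 3 and
above = the risk was quantified, 5 = patient-centered and
patient-specific. The schema enforces that a positive grade implies the
label and that an unset label implies grade 0. By default only physician
sentences may carry labels (physician quotes are what is coded); a flag
relaxes this. The full wording of intermediate levels 1, 2, and 4 is
deliberately configurable (`grading.QUALITY_LEVELS`) rather than fixed.

The consultation-level **actual** quality score for a concept is the
maximum grade over all of its sentences. The **model-predicted** score
is the maximum grade over only the K sentences with the highest
classifier probability of topic concordance. The predicted score is a
subset maximum, so it is bounded above by the actual score, reaches it
exactly when K covers the consultation, and its accuracy is
non-decreasing in K. These invariants are tested unconditionally.

## Pipeline

1. **Segmentation** is rule-based: boundaries at `. ! ?` followed by
   whitespace, guarded by a fixed abbreviation list (Dr., Mr., vs.,
   e.g., i.e., No., …). No statistical splitter is used, so output is
   bit-reproducible.
2. **Splitting** is at sentence level, 75/25 by default, training size
   `floor(0.75·N)` (28,927 sentences → 21,695 / 7,232). Sentence-level
   splitting lets one consultation contribute to both subsets; a
   consult-level mode (`by_consult=True`) is available for users who
   want to rule out within-consult leakage.
3. **Features** are raw counts of Snowball-English (Porter2) word stems:
   lowercase → strip punctuation and digits-only tokens → whitespace
   tokenize → remove a frozen 318-word English stop list shipped with
   the package → stem. The stemmer is implemented in-package and checked
   against hand-traced reference outputs. Unigrams only and raw counts
   by default (sentences are short; no weighting is assumed); TF-IDF and
   n-grams are options. The vocabulary keeps stems occurring in at least
   2 training sentences (`min_document_frequency=2`), sorted
   lexicographically, and is fit on the training split only.
4. **Models.** One independent binary classifier per concept, six
   families: random forest, decision tree, elastic-net logistic
   regression (saga, l1_ratio 0.5, C 1.0), RBF support vector machine
   with Platt-scaled probabilities, gradient boosting (xgboost), and
   unpenalized logistic regression. Hyperparameters are the backing
   libraries' defaults, recorded into the model spec at fit time. The
   random forest uses 100 trees, scikit-learn's default; at this corpus
   scale (~140 stem features) cross-validated AUC is indistinguishable
   from larger forests while being several-fold faster. No resampling or
   class weighting is applied at the 0.3–2.4% prevalences; a
   class-weight option exists via the hyperparameter map.
5. **Family racing.** Families are ranked per concept by mean ten-fold
   cross-validated AUC on the training split; folds are stratified
   (unstratified folds can contain zero positives at 0.3% prevalence)
   and seed-controlled. The overall champion is the family with the best
   mean rank across the nine concepts; ties break by the fixed family
   enumeration order (random forest first). The CV confidence interval
   is mean ± 1.96·SE across folds; a percentile bootstrap is used for
   validation-set AUCs instead.
6. **Thresholds.** Each concept's operating threshold maximizes
   Youden's J = sensitivity + specificity − 1 over candidate thresholds
   (midpoints of consecutive distinct scores, plus the minimum score).
   Classification is `score ≥ threshold`; ties in J break toward the
   lower threshold, favoring sensitivity for screening use. Ratios with
   zero denominators (e.g. PPV with no predicted positives) are
   reported as explicitly unset, never as 0 or 1.
7. **Grading.** Top-K extraction (K = 10 working default; 5/10/15/20 in
   the sensitivity table) with ties broken by earlier sentence
   position. Agreement between predicted and actual consult scores is
   summarized per concept by a 6×6 confusion matrix and micro-averaged
   one-vs-rest metrics over the fixed six levels, including levels
   absent from the data. Under this convention micro-sensitivity =
   micro-PPV = accuracy and micro-specificity = micro-NPV =
   1 − (1 − accuracy)/5, which makes every agreement row derivable from
   its accuracy alone; per-level metrics are available secondarily.
   Aggregate capture rates use a strict inequality (probability
   strictly greater than the cutoff) over sentences graded 3+, and the
   probability–quality association is an OLS regression of grade on
   predicted probability (per concept by default; pooling is a caller
   choice).

## Synthetic corpora

No public corpus of coded consultations exists, so the generator
(`synthgen`) emulates the development dataset's statistical shape:

- 50 consultations, negative-binomial lengths with mean 578.54
  (≈28,927 sentences total; dispersion 25), plus an independent
  20-consultation validation set with mean length 468.35 (≈9,367
  sentences), generated from a separate seed stream with disjoint ids.
- Per-sentence concept prevalences (TR…LUTS) of 1.2, 2.4, 0.4, 1.2,
  0.3, 0.3, 2.1, 1.2, 1.0 percent, drawn i.i.d. per sentence; at most
  one concept per sentence by default (`allow_multi_concept` relaxes
  this).
- Topical sentences draw a grade from {1: .35, 2: .25, 3: .20, 4: .12,
  5: .08} — most mentions unquantified, as in real consultations — and
  their text mixes filler words with 1–3 concept keywords; grade-3+
  sentences add quantification words and grade-5 sentences add
  patient-specific framing, so predicted probability rises with grade.
- `noise_rate` (default 0.05) renders that fraction of topical
  sentences without their lexicon: label noise in the features that
  keeps classifiers imperfect, bounding attainable AUC below 1 the way
  paraphrase does in real speech.
- Keyword lexicons are invented, stem-disjoint fixtures with face
  validity (e.g. gleason/biopsy for pathology results); they are not
  measured from any real corpus. Separate deterministic seed streams
  drive structure, text assembly, and noise.

What passing on these corpora shows: the pipeline recovers planted
signal at realistic prevalence and sample sizes, the protocol's
invariants hold, and the whole workflow is reproducible under seeds.
What it does not show: performance on real clinical language —
synthetic sentences are token salads with disjoint lexicons, no
grammar, discourse structure, negation, multi-concept sentences, or
within-consult topic clustering.

## Problem sizes for racing and cross-validation

Family racing and the champion's per-concept CV run on fixed-size
random subsamples of the training split (defaults: 4,000 sentences for
the six-family race, 6,000 for the champion's CV), because a kernel SVM
cannot be ten-fold cross-validated at twenty thousand sentences in
reasonable time and relative family rankings are stable under
subsampling. The subsampler tops up any concept whose positives would
fall below the fold count, so stratified folds always exist. Final
champion models are always fit on the full training split, and
thresholds, validation AUCs, and all grading results use full-size
data.

## Numerical and degenerate-input choices

- AUC is computed as the Mann–Whitney statistic (ties count half) and
  equals the trapezoidal area under the ROC curve; both routes are
  tested against exhaustive pair counting.
- Bootstrap CIs resample positives and negatives separately
  (stratified percentile, 2,000 replicates by default) so every
  replicate keeps both classes at sub-percent prevalence.
- Single-class label vectors, constant predictors, empty corpora, and
  vocabulary/column mismatches raise informative errors rather than
  returning degenerate numbers.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical seeds give
  byte-identical corpora and identical fold assignments, fits, and
  bootstrap intervals.

## Known limitations

- The quality evaluation is deliberately not fully automated: the top-K
  protocol ranks sentences, and the 0–5 grading of those K sentences
  remains a manual step in the intended use; on synthetic corpora the
  generator's grades stand in for that manual grading.
- One model per concept ignores correlations between concepts.
- The synthetic generator's simplifications listed above mean measured
  AUCs/accuracies on it characterize the method under its assumptions,
  not expected real-world performance.
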
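"""Race model families, train per-concept classifiers, pick thresholds.

The development corpus is split 75/25 at sentence level; six families are
compared by mean ten-fold cross-validated AUC per concept, the champion
is refit on the full training split, and each concept gets a Youden
(J-index) operating threshold from the internal validation split.
Scaled down (3 families, 5 folds, small corpus) to finish in ~a minute.
"""

from consultnlp import CONCEPTS
from consultnlp.synthgen import DEFAULT_PREVALENCE, GeneratorConfig, generate_corpus
from consultnlp.workflow import run_training

config = GeneratorConfig(
    n_consults=10,
    sentences_per_consult=(250, 20),
    prevalence={c: 3 * p for c, p in DEFAULT_PREVALENCE.items()},
    seed=42,
)
corpus = generate_corpus(config)

run = run_training(
    corpus,
    seed=42,
    families=("random_forest", "elastic_net", "logistic"),
    folds=5,
    race_subsample=1200,
    cv_subsample=1500,
    bootstrap_replicates=300,
)

print(f"champion family: {run.champion_family}\n")
print("concept  cv_auc  valid_auc  (95% CI)          threshold  sens  spec")
for c in CONCEPTS:
    lo, hi = run.validation_auc_ci[c]
    d = run.diagnostics[c]
    print(
        f"{c.value:7s}  {run.champion_cv[c].mean_auc:.3f}   {run.validation_auc[c]:.3f}"
        f"  ({lo:.3f}-{hi:.3f})   {run.models[c].threshold:8.3f}  {d.sensitivity:.2f}  {d.specificity:.2f}"
    )
print(
    "\ncv_auc: champion's cross-validated AUC on the training split;"
    "\nvalid_auc: AUC on the held-out 25% with a stratified bootstrap CI;"
    "\nthreshold: probability cutoff maximizing sensitivity + specificity - 1."
)
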
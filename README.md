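# phenoforge

Computable phenotyping from primary-care electronic medical records:
build, simplify and validate **case definitions** — machine-evaluable
rules that decide, from the contents of a patient chart, whether the
patient has a condition.

The package targets the multi-table chart shape of Canadian primary-care
EMR repositories (billing claims, encounter diagnoses, problem list,
medications, referrals; ICD-9-CM and ATC codes plus short diagnostic
free text), and ships a synthetic cohort generator with a *planted*
ground-truth rule so the whole pipeline can be exercised, calibrated and
tested without access to confidential patient data. The worked default
is the phenotype of *problematic menopause* in women aged 45–60: the
kind of condition that only becomes visible in EMR data through repeated
coded diagnoses (ICD-9 627\*), hormone-therapy prescriptions (ATC
G03CA\*), and free-text mentions that may be negated or uncertain.

## What it computes

**Rule engine.** A `CaseDefinition` is an OR of clauses
"≥ *k* matches of a code prefix or text term within a rolling window of
*w* months among sources *S*". Sub-codes are string-prefix matches on
normalised codes; "within 24 months" is a rolling 730-day window;
negated or uncertain text mentions ("not menopause", "menopause?",
"rule out menopause", 50 shipped templates) never fire a text clause.
Evaluation is monotone: adding records can only turn a non-case into a
case.

**Validity statistics.** Sensitivity, specificity, PPV and NPV with
Wald (default), Wilson or Clopper–Pearson intervals; the F1 score

    F1 = 2 (1/Sn + 1/PPV)^-1

used as the training optimisation metric; the Wald validation-set size

    N = 1.96² · Sn(1−Sn) / ((c/2)² · p)

for a target sensitivity CI width *c* at prevalence *p*; and Fleiss's
kappa for multi-reviewer chart-label agreement.

**Feature engineering.** Every code prefix and every free-text word and
adjacent word pair becomes a binary feature in four temporal variants
(≥1 anywhere; ≥2 within 12 months; ≥2 within 24 months; ≥2 anywhere).
Features present in fewer than 10 patients are dropped; an ad hoc
importance score, (TP − FP)/cases, prescreens to the top 300.

**Learner.** Nested 10×10-fold cross-validation compares 14
combinations of class rebalancing (none, random over-, random under-,
combined) × feature reduction (recursive feature elimination, k-best)
× order of application, tuning CART decision-tree hyperparameters on
inner folds by F1. The best combination is retrained on the full
train/test half; the tree's features are ranked by impurity importance
and every singleton and OR-pair of the top nine becomes a candidate
simplified definition. The winner is scored once on an untouched
validation half (leakage is asserted programmatically).

## Worked example

`examples/05_end_to_end.py` runs the whole pipeline on a 600-patient
synthetic cohort (a few seconds):

```
best combination: RFE;random over- & under-sampling (mean F1 1.000)
final tree importances:
  0.7063  code_prefix:G03CA|ge1
  0.2937  code_prefix:627|ge2_24mo

chosen case definition: >=1 x code_prefix 'G03CA' OR >=2 x code_prefix '627' within 24 months
validation half (n=300): sensitivity 100.0% (100.0-100.0%), specificity 100.0% (100.0-100.0%)
```

The pipeline recovered exactly the two clauses the generator planted —
one estrogen prescription, or two menopause diagnoses within 24
months — and the definition classifies the held-out half perfectly
because this synthetic cohort was generated with separable signal. On
noisier configurations (see `CohortConfig`) the validation block
quantifies the degradation. The other examples cover sample-size
planning and reviewer agreement (`01`), hand-built charts and validity
metrics (`02`), cohort generation and summaries (`03`), and the feature
matrix with its importance prescreen (`04`).

A thin CLI wraps the same calls:

```sh
phenoforge simulate --seed 3 -o cohort/          # CSV chart tables
phenoforge featurize cohort/ -o features/        # sparse feature matrix
phenoforge run-all --seed 3 -o run/              # full pipeline + reports
phenoforge validate run/case_definition.yaml cohort/
```

`run-all` writes the combination table, the importance table, the
chosen definition as YAML, the validation report, a cohort summary and
a manifest with seed, config hash and per-stage timings.

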
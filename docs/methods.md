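# Methods

This note records the model, the synthetic data-generating process, the
numerical choices, and the design decisions taken where the problem was
genuinely open. It describes what the code does and why; every number
quoted here is computed by the test suite or the examples, not asserted
from elsewhere.

## The phenotyping problem

A case definition is a Boolean rule over a patient chart. Charts are
multi-table: billing claims, encounter diagnoses, problem-list entries
(all three carrying ICD-9-CM codes and/or short free text), prescribed
medications (ATC codes) and referrals (free text only). The rule must
be evaluable by a database query — no model artefacts at deployment —
which is why the pipeline ends in an OR of at most two clauses rather
than a fitted classifier.

### Clause semantics

A clause is "≥ *k* matches of a pattern within window *w* among sources
*S*".

* **Windows.** "Within 12/24 consecutive months" is implemented as a
  rolling window of 365/730 days between the earliest and latest of
  some *k* qualifying records. Calendar-month arithmetic is ambiguous
  (month lengths, end-of-month anchoring); the rolling form is
  unambiguous, order-free, and monotone in chart content. For sorted
  dates the optimal size-*k* subset is always *k* consecutive dates, so
  a linear scan is exact; the test suite proves this against exhaustive
  subset enumeration on charts with up to 8 matching records.
* **Sub-codes.** "Code 627 or any sub-codes" is a string-prefix match
  after stripping dots/whitespace and upper-casing, so `627.2`, `6272`
  and `627` all normalise consistently. ATC matching is the same
  mechanism.
* **Monotonicity.** A definition is an OR of clauses and each clause's
  count can only grow with added records, so a case verdict can never
  be revoked by new data — a property test asserts this.

### Negation and uncertainty in free text

Chart free text is short (≤255 characters) and telegraphic. Mentions of
the target condition inside a negated or uncertain construction must
not fire a rule. The package ships a 50-template lexicon — negation
cues ("not", "no", "denies", "without", "ruled out", "r/o", "negative
for", ...) and uncertainty cues (a trailing "?", "query", "possible",
"suspected", ...) — applied mention-by-mention: only the target term in
the matched construction is removed, so an affirmative mention
elsewhere in the same text survives. The published source of this
design gives only three exemplar constructions; the remaining 47 are
this package's own curation of common chart shorthand and are
configuration, not a fixed vocabulary. Tokenisation lower-cases and
splits on punctuation except that a `?` stays attached to its preceding
token, because the trailing question mark is itself the uncertainty
marker.

## Validity statistics

Sensitivity, specificity, PPV and NPV are the four cells of the
confusion matrix normalised by row or column. Choices:

* **Zero denominators** yield an *undefined* metric (`None`), never a
  silent 0 — an all-negative prediction vector should not report
  "PPV 0%" as if it had been measured.
* **Confidence intervals** default to Wald (clipped to [0,1]) for
  consistency with the Wald sample-size formula; Wilson and
  Clopper–Pearson are selectable because published interval choices are
  often unstated and Wald is known to be anti-conservative near 0/1.
* **F1** is the harmonic mean of sensitivity and PPV, extended
  continuously to 0 when either input is 0. Note that the mean of
  per-fold F1 values is not the harmonic mean of the mean sensitivity
  and mean PPV except in the single-fold case; the cross-validation
  report exposes both quantities (`mean_f1` and `f1_of_means`).
* **Sample size** uses N = z²·Sn(1−Sn)/((c/2)²·p) and returns the
  ceiling, the conservative reading when no rounding rule is stated.
* **Fleiss's kappa** is implemented directly from the subjects ×
  categories count table; the degenerate case where all ratings fall in
  one category (chance agreement P̄e = 1) is defined as κ = 1, the
  all-agree limit. A test cross-checks the implementation against
  statsmodels on random tables.

## Synthetic cohort generator

The generator emulates the *structure* of a primary-care extract, not
the marginal distributions of any real repository. Defaults define the
study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| n_patients | 2,776 | reference study-sample size |
| prevalence | 0.19 | preliminary-search estimate for the phenotype |
| ages | uniform 45–60 | the study's inclusion window |
| date span | 2011-01-01 – 2020-12-31 | ten years of "EMR-era" records |
| records/patient | negative binomial, mean 15, dispersion 1.5 | overdispersed desk-scale chart volume; no published per-chart volume exists |
| reviewers | 5, error rate 0.04 | five independent flips + majority vote; 0.04 yields kappa in the mid-0.8s on review-sized subsets, matching a "good to excellent" panel |
| unclassifiable rate | 1/2,776 | one chart per reference cohort |
| text noise rate | 0.10 | fraction of planted affirmative mentions degraded to filler |
| negation rate | 0.15 | fraction of non-cases receiving negated/uncertain mentions |
| sub-threshold rate | 0.10 | non-cases with a *single* 627\* code |
| spaced-pair rate | 0.05 | non-cases with two 627\* codes > 24 months apart |

True cases satisfy the planted definition by construction (ICD-9 627\*
pairs spanning 30–700 days, and/or one or two G03CA\* prescriptions);
non-cases never do. Three kinds of *near-miss* structure make the
learning problem non-trivial and make the planted clause parameters the
genuinely discriminating ones:

* single 627\* codes (sub-threshold count),
* 627\* pairs spaced beyond the 24-month window (so the
  whole-chart variant of the pair feature has false positives and the
  24-month variant is strictly better),
* rare non-case G03-class prescriptions — contraceptives (G03AC, G03AA)
  and a synthetic estrogen (G03CB) — so every coarser ATC prefix (G03,
  G03C) is impure and the planted G03CA depth is strictly better.

Background records draw chronic-condition codes from eleven ICD-9
families (kidney disease, COPD, dementia, depression, diabetes,
dyslipidemia, epilepsy, herpes zoster, hypertension, osteoarthritis,
parkinsonism), acute-complaint codes, distractor prescriptions, and
zipf-weighted filler text over a fixed 240-word vocabulary (clinical
words plus pronounceable pseudo-terms). At study scale this yields
~8×10⁴ generated features before support filtering, the right order of
magnitude for short-text bag-of-words feature spaces.

What the generator does **not** model: provincial billing dialects,
care-seeking trajectories, coding drift over time, correlated reviewer
errors, or realistic marginal code frequencies. Passing tests therefore
demonstrate pipeline correctness (the machinery recovers a rule that is
truly in the data), not clinical performance on real charts.

All randomness flows from a single integer seed through named
substreams (cohort structure, reviewers, split, folds, resampling, tree
seeds), so identical configurations reproduce byte-identical artefacts.

## Feature engineering

Each feature base is a (kind, pattern, scope) triple: code prefixes
(ICD-9 at every prefix length ≥ 3; ATC at the hierarchy boundaries 3,
4, 5, 7), free-text unigrams and adjacent bigrams (within one record
only — records are independent short texts). Scope follows the code
system: diagnosis sources for ICD-9, medication for ATC, all
text-carrying sources for text. Each base expands to four binary
temporal variants. Two filters follow:

* **minimum support**: a feature must be positive in ≥ 10 *patients*
  (not records);
* **prescreen**: the ad hoc importance (TP − FP)/P, computed per
  training fold, keeps the top 300 columns; ties break
  lexicographically by feature name so selection is reproducible.

Every matrix column is reproducible by evaluating its feature spec as a
clause against the raw charts; a test asserts this column-by-column.
The prescreen is computed inside each outer training fold rather than
once globally — the conservative reading that avoids using test-fold
labels in any selection step.

## Learner

The classifier is CART (scikit-learn `DecisionTreeClassifier`), chosen
for rule extractability; black-box ensembles are out of scope by
design. The hyperparameter grid (branching criterion, branching
strategy, depth, minimum samples per leaf, class weights) is editable
configuration. Two grids ship: a full grid (2×2×6×4×4) and a desk-scale
grid (criterion × depth {4, none} × class weight {none, balanced}) used
by the tests and examples so the nested procedure — not grid breadth —
dominates runtime. Problem sizes in the tests (n = 2,776 cohorts,
10×10-fold nested CV, ten recovery seeds) were chosen as the package's
desk-scale defaults.

Nested CV details and deliberate choices:

* **14 combinations**: 4 resamplings × 2 reducers × 2 orders, with the
  two order-variants of "no resampling" collapsed (they are identical).
* **Resampling** definitions: under-sampling drops non-cases to the
  case count; over-sampling duplicates cases to the non-case count;
  "combined" meets at the rounded geometric mean of the class sizes —
  the meeting point is not prescribed anywhere, and the geometric mean
  treats both classes symmetrically on the ratio scale. Resampling is
  applied to training splits only; test folds and the validation half
  are never resampled.
* **Reduction**: RFE refits the tree and drops the lowest-importance
  30% per round down to 25 columns; k-best keeps the 25 columns with
  the highest chi-squared association (non-negative binary features
  make chi-squared the natural univariate score; the published method
  names the selector but not its score).
* **Placement compromise**: the prescreen and the reducer are fitted
  once per *outer* training fold (in the combination's order), while
  resampling is re-applied inside each inner fold to the inner training
  split only. Refitting RFE inside every inner fold would multiply the
  tree-refit chains tenfold for a decision that only affects
  hyperparameter selection; outer-fold test data remain untouched
  either way.
* **Selection metric**: "highest average validation metrics" is
  operationalised as mean outer-fold F1 with mean sensitivity, then
  mean PPV as tie-breaks — F1 is the stated optimisation metric and the
  two tie-breaks preserve the screening-oriented priority (catch cases
  first, then precision).
* **Inner folds with a single class** are skipped with a logged
  warning rather than crashing the grid search.

## Simplification

The final tree's features are ranked by impurity importance
(normalised to sum to 1). From the top *s* = 9, the pipeline builds all
9 singleton and C(9,2) = 36 pair definitions — 45 candidates in total;
pairs combine with OR because the target artefact is a disjunctive
rule. Candidates are scored on the full train/test half; the selection
metric is the same F1/Sn/PPV cascade, with two further tie-breaks:
fewer clauses (prefer the simpler rule), then feature name (determinism).
Candidate evaluation goes through the feature-matrix columns, which the
column-reproducibility oracle guarantees is identical to rule-engine
evaluation; the chosen definition is finally scored on the validation
half through the rule engine itself.

## Degenerate inputs and edge cases

* Empty chart → every clause false.
* Constant labels → a single-leaf tree with no rules and no
  importances (training proceeds without prescreen or tuning).
* min_count = 1 clauses require a whole-chart window (a one-record
  window is meaningless) — enforced at construction.
* Unclassifiable charts are excluded before splitting, so confusion
  matrices only ever see case/non-case labels; passing one through is
  an error, not a silent drop.
* An unsatisfiable planted definition (date span shorter than the
  records a clause needs) is rejected at configuration time.

## Known limitations

* The negation matcher is template-based (token-window matching); it
  does not handle long-range scope ("no evidence of X or Y") beyond
  the shipped templates.
* Feature scopes are code-system-wide: ICD-9 features pool billing,
  encounter-diagnosis and problem-list sources rather than generating
  per-source duplicates. Source-specific rules can still be expressed
  and evaluated, but are not learned.
* The combined-resampling meeting point, the k-best score, and the
  hyperparameter grid are reasoned defaults, not published values;
  all are configuration.
* Synthetic validation metrics near 1.0 reflect the separability of the
  planted signal, not expected real-data performance.
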
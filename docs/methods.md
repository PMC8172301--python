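# Methods

This note documents the modelling choices behind `caremine`: what each
stage assumes, the defaults and why, what the synthetic cohorts do and
do not emulate, and the numerical conventions.

## Trajectories and contexts

A trajectory is an ordered list of itemsets of event codes. Temporal
order is an abstract non-negative integer rank supplied by the caller
(a month number, a stay rank): the package deliberately contains no
calendar parsing, so the miner is independent of how stays were dated.
Codes sharing a rank form one itemset.

Covariates are discretized with left-inclusive boundaries — age exactly
65 falls in the 45–65 class and exactly 5 stays in the ≤5 class —
matching the printed class labels. Patients aged ≤45 are outside the
inclusion window and rejected at discretization. Patients who lose
every stay under relevance filtering are dropped rather than kept as
empty sequences, since every later stage requires non-empty
trajectories.

The context hierarchy is the full 3 × 3 × 3 lattice over sex, age
class and stay class (each attribute fixed or free), 27 contexts.
Sparse contexts are *flagged*, not removed: exclusion is a
configuration screen (`min_patients`, `min_events_per_class`) rather
than a hard-coded list of names, because which cells are too sparse
depends on the cohort at hand.

## Mining

Embedding semantics are standard sequential-pattern semantics: pattern
itemsets map to strictly increasing trajectory positions with itemset
containment. Support counts patients, not occurrences. The frequency
decision `support ≥ minsup` is made in exact rational arithmetic
(`count_needed = ceil(minsup · n)` on a `Fraction`), so thresholds like
2/3 cannot be misclassified by floating-point rounding at the boundary.

The miner grows patterns depth-first PrefixSpan-style — sequence
extension appends a new single-item itemset, itemset extension adds a
lexicographically larger item to the last itemset — and carries the set
of supporting sequences down the recursion (pseudo-projection):
anti-monotonicity guarantees a candidate's supporters are a subset of
its parent's, so each candidate is counted only against that subset.
Each pattern is generated exactly once because deleting its last added
item yields a unique canonical parent. The engine supports multi-item
itemsets, but the default configuration (`max_itemset_size = 1`) mines
single-item itemsets: filtered stay trajectories are effectively one
code per time position, and single-item patterns are what the
featurization consumes.

Maximal filtering retains exactly the patterns not embedded in another
pattern of the set; it is idempotent and its output is pairwise
incomparable. Output ordering is canonical (support descending, then
pattern text), which fixes downstream feature-column order.

A configurable cap (`max_patterns`, default 100,000) aborts pathological
runs with guidance to raise `min_support`.

## Similarity

Distances operate on **tokens** — one token per event code, itemsets
flattened in sorted order — never on the characters of multi-character
codes. Character-level comparison would conflate code similarity (I21
vs I25 share two characters) with sequence similarity, which is not
what "similarity between patterns of care" means.

Per-measure conventions:

- *longest common substring* is the contiguous-run definition (per the
  measure's name in the standard string-distance taxonomy), with
  distance |a|+|b|−2·LCSstr and similarity normalized by |a|+|b|;
- Levenshtein / OSA / Damerau–Levenshtein similarities normalize by
  max(|a|,|b|);
- the q-gram family uses q = 2 (trajectories are short; longer grams
  would empty most profiles); L1 profile distance normalizes by total
  profile mass; Jaccard and cosine are already in [0,1];
- Jaro–Winkler uses the universal prefix scale 0.1 with prefix cap 4.

Degenerate inputs are total by convention: two empty token texts (or
two empty q-gram profiles) are maximally similar; one empty profile
against a non-empty one gives similarity 0. These conventions are
exercised directly by the tests.

Discretization maps similarity to low (<0.4), medium, strong (≥0.6).

## Prediction protocol

The cohort is split once into internal (default fraction 3245/4871)
and external parts; the external part is untouched until the final
validation. Patterns are mined from **internal patients only**, so no
information from the external split leaks into the features.

Internal validation uses R repeated stratified holdout rounds (default
R = 5; the end-to-end tests use 3) with the train fraction 2163/3245.
Both the training and the internal test sample are balanced on the
outcome by uniform undersampling of the majority class, mirroring the
protocol's balanced training/test sets; the reported "predicted deaths"
is the mean count of predicted-death test cases across rounds, which is
why it is fractional. Stratification keeps both outcome classes in both
halves of every round. All metrics are averaged over rounds (the mean
is the aggregation; the number of rounds is configurable).

Classifier defaults (all overridable through `ModelConfig`
hyperparameters): Gaussian naive Bayes for continuous features and
Bernoulli factors over the one-hot expansion for discretized ones
(equivalent to a per-feature categorical NB); KNN with k = 5; decision
tree with cost-complexity pruning, the alpha chosen by internal 3-fold
cross-validation over the pruning path; unpenalized logistic
regression; radial-kernel SVM with C = 1 and Platt-style sigmoid
calibration for probabilities; a single-hidden-layer perceptron with
max(3, k) units and weight decay 0.01. KNN, SVM and ANN see
standardized features. Hard predictions threshold the death probability
at 0.5, the natural cut on balanced training data.

Selection is maximal-vector computation over (AURC ↑, F-measure ↑,
error rate ↓) by default — the three criteria the protocol reports —
configurable to all seven metrics. When the front contains several
configurations the package reports the whole non-dominated set and
nominates one deterministically (lexicographic by the criteria in
order, then by configuration name). The nominated configuration is
refitted on the full balanced internal part and validated once on the
external split, unbalanced as observed; AURC is flagged undefined if
the external split lacks a class, while the Brier score is still
reported.

AURC is the trapezoidal area under the ROC curve, identical to the
Mann–Whitney formulation with half credit for ties; the test suite
verifies it against exhaustive pair counting. Ratios with zero
denominators (e.g. precision with no positive predictions) are reported
as 0 and flagged rather than raising, so a degenerate round cannot
abort a study.

## Synthetic cohorts

The generator emulates the structure of an administrative discharge
cohort: ~5,000 patients by default, 40% women, 60% over 65, 4–10
single-code stays drawn from a 12-code vocabulary, one length-3 risk
pattern per age class planted with probability 0.35, and death drawn
from logistic(−3.2 + 4 · maxsim) where maxsim is the patient's maximal
Levenshtein similarity to the risk patterns applicable to them. The
intercept and slope were set so that overall death prevalence lands
near the ~14% of the real cohort the structure mirrors. The 12-code
vocabulary and length-3 patterns keep chance embeddings near 1–2%, so
mined supports recover planting probabilities within the 3-standard-
error binomial band at n = 2000.

Outcome depends on *similarity*, not on a planted flag, so the string
measures sit on the causal path: a featurization bug degrades
downstream discrimination and is caught by the end-to-end tests.

Two fixed presets support the end-to-end checks. `strong_signal` uses
length-4 trajectories, an 8-code vocabulary, one universal length-2
risk pattern planted at 0.5 and a steep logistic (−11 + 30·maxsim).
The steepness is forced by the arithmetic of a Bernoulli outcome: with
planted-trajectory death probability p₁ and background p₀, the
achievable AURC is bounded by the class mixture, and only
near-deterministic probabilities (p₁ ≈ 0.98, p₀ ≈ 0.03 here) push the
bound above 0.9. `null` sets the coefficient to 0 with prevalence
pinned at 14%, so any external AURC away from 0.5 would indicate
leakage. The end-to-end runs use 1,500-patient cohorts and a reduced
configuration grid (SVM/LR × Levenshtein × continuous, general
context), sizes chosen to keep the full verification suite fast while
leaving the binomial error bands comfortably narrow.

What the generator does **not** emulate: calendar time and seasonality,
comorbidity structure and code co-occurrence, transfers and competing
risks, context-correlated trajectory lengths, and ICD-hierarchy
relatedness between codes. Passing tests therefore demonstrate that the
machinery is correct and that the protocol recovers planted structure —
not that comparable discrimination will be achieved on real discharge
data, where signal strength is an empirical question.

## Known limitations

- The miner is exact but enumerative; with very low support thresholds
  on long-trajectory cohorts the pattern count (and the `max_patterns`
  cap) is the practical limit, not time per pattern.
- No gap constraints, time-stamped patterns, or closed-pattern mining;
  no semantic (ICD-hierarchy) code similarity; no ensemble model
  families, feature selection, or hyperparameter search.
- Bootstrap confidence intervals for external metrics are not
  implemented; the report tables carry point estimates and, for the
  model-by-family summary, normal-approximation 95% CIs across
  configurations.
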
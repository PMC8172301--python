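# caremine

Contextual sequential pattern mining and similarity-based prediction of
in-hospital mortality from coded hospital care trajectories.

## The problem

Administrative hospital databases record, for every patient, a
time-ordered sequence of coded stays — ICD-10 diagnosis codes or DRG
stay-group codes. For conditions such as acute coronary syndrome, the
*shape* of that care trajectory carries prognostic information: certain
recurring patterns of stays are associated with in-hospital death.
`caremine` implements a complete protocol for exploiting this signal:

1. **Trajectories** (`caremine.trajectory_db`). Stay-level records are
   filtered to condition-relevant codes and grouped into per-patient
   sequences of itemsets; patients are stratified into *contexts* —
   conjunctions over sex, age class (45–65 / >65 years) and stay-count
   class (≤5 / >5 stays), 27 contexts in all including the general one.
2. **Contextual mining** (`caremine.pattern_mining`). For a sequential
   pattern *P* and context *c*, support is the fraction of *c*'s
   patients whose trajectory embeds *P* as a subsequence,
   supportc(*P*) = |{patients of *c* embedding *P*}| / |*c*|.
   Patterns with supportc(*P*) ≥ minsup are mined by PrefixSpan-style
   prefix-projected growth, then reduced to the *maximal* frequent
   patterns (those not embedded in another frequent pattern) to avoid
   collinear predictors.
3. **Similarity features** (`caremine.similarity`). Each trajectory
   T_P is compared with its context's patterns s₁..s_k under nine
   token-level string measures in three families — edit-based (longest
   common substring, Levenshtein, optimal string alignment,
   Damerau–Levenshtein), q-gram (q-gram, Jaccard, cosine) and heuristic
   (Jaro, Jaro–Winkler) — giving the feature vector
   sim_P = (sim(T_P, s₁), …, sim(T_P, s_k)) ∈ [0,1]^k,
   used either continuously or discretized to low (<0.4) /
   medium / strong (≥0.6).
4. **Prediction and selection** (`caremine.prediction`,
   `caremine.evaluation`). Six classifier families (NB, KNN, Tree, LR,
   SVM, ANN) × nine measures × two encodings = 108 configurations per
   context are trained on balanced samples under repeated stratified
   holdout, scored by accuracy, sensitivity, specificity, error rate,
   precision, F-measure and AURC, and the best (model, similarity)
   compromise is chosen by maximal-vector (Pareto skyline) computation.
   The selected model is validated once on an untouched external split
   with AURC and the Brier score.

Because the real discharge data behind this protocol is
access-restricted, `caremine.synthetic_data` generates cohorts with the
same structure — planted context-specific risk patterns and a logistic
death model driven by trajectory–pattern similarity — with full ground
truth for verification.

Intended users: biostatisticians and epidemiologists working with
administrative care-pathway data who want pattern-based, interpretable
predictors rather than black-box sequence models.

## Worked example

```python
from caremine import (GeneratorConfig, generate_cohort, StudyConfig, run_study,
                      MiningConfig, SimilarityMeasure)

db, truth = generate_cohort(GeneratorConfig.strong_signal(n_patients=1500, seed=3))
study = StudyConfig(
    mining=MiningConfig(min_support=0.2),
    families=("SVM", "LR"),
    measures=(SimilarityMeasure("levenshtein"),),
    encodings=("continuous",),
    n_repeats=3,
    context_labels=("general",),
)
result = run_study(db, study, seed=3)
[cr] = result.per_context
best = cr.selected
print("patterns mined:", [p.to_text() for p in cr.patterns.patterns[:3]], "...")
print(f"selected: {best.configuration.name}")
print(f"internal AURC {best.metrics.aurc:.3f}  error rate {best.metrics.error_rate:.3f}")
print(f"external AURC {best.external_aurc:.3f}  Brier {best.brier:.3f}")
```

Output:

```
patterns mined: ['<(R07)(I20)>', '<(I48)>', '<(I50)>'] ...
selected: SVM+levenshtein+continuous
internal AURC 0.994  error rate 0.009
external AURC 0.981  Brier 0.027
```

The cohort plants the chest-pain → angina pattern `<(R07)(I20)>` in
half the patients and makes death nearly deterministic given high
similarity to it; the miner recovers the pattern (support 0.51 =
planting rate plus chance embeddings), the Pareto rule selects the
radial-kernel SVM on Levenshtein similarities, and the model
discriminates almost perfectly on the untouched external third of the
cohort (AURC 0.98) with good overall accuracy (Brier 0.03).

Real data enters through a stay-level CSV
(`patient_id,order_index,code,code_system,sex,age,outcome`, one row per
code per stay) via `caremine.load_cohort_csv`.

## Layout

```
src/caremine/
  trajectory_db.py    records, trajectories, covariates, contexts
  pattern_mining.py   embedding, support, PrefixSpan growth, maximal filter
  similarity.py       the nine token-level string measures, vectors
  prediction.py       splits, balancing, features, six classifiers, study runner
  evaluation.py       metrics, Pareto selection, ranking, external validation
  synthetic_data.py   ground-truth cohort generator
docs/methods.md       modelling assumptions, defaults, limitations
```
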
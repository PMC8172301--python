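"""Dataset preparation, classifier training and study orchestration.

The modelling protocol:

1. the cohort is split patient-wise into an *internal* part (training +
   internal validation; default fraction 3245/4871) and an *external*
   part kept untouched until final validation;
2. within each context, repeated stratified holdout rounds split the
   internal part into training and test sets (default fraction
   2163/3245), both balanced on the outcome by uniform undersampling of
   the majority class;
3. six classifier families (NB, KNN, Tree, LR, SVM, ANN) are trained on
   similarity features under each of the nine string measures and two
   encodings (continuous or low/medium/strong discretized), i.e. 108
   configurations per context;
4. internal metrics are averaged over rounds; the best (model,
   similarity) compromise per context is chosen by maximal-vector
   computation and refitted on the full balanced internal part before
   external validation.

All randomness is driven by explicit integer seeds threaded through
splitting, balancing and training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import evaluation
from .pattern_mining import ContextPatternSet, MiningConfig, mine_contextual_maximal
from .similarity import (
    SimilarityConfig,
    SimilarityMeasure,
    all_measures,
    discretize_similarity,
    encode,
    similarity,
)
from .trajectory_db import (
    DEAD,
    Context,
    SequentialDatabase,
    discretize_covariates,
    enumerate_contexts,
)

logger = logging.getLogger("caremine")

FAMILIES = ("NB", "KNN", "Tree", "LR", "SVM", "ANN")
ENCODINGS = ("continuous", "discretized")


class SplitError(ValueError):
    """Raised when a split or balance request cannot be honoured."""


class TrainingError(RuntimeError):
    """Raised when a configuration fails to train (flagged, not fatal)."""


@dataclass(frozen=True)
class SplitPlan:
    """Internal/external and train/test split fractions.

    Defaults reproduce the study proportions: 3245 of 4871 patients
    internal, of which 2163 of 3245 train in each holdout round.
    """

    internal_fraction: float = 3245 / 4871
    train_fraction: float = 2163 / 3245
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.internal_fraction < 1 or not 0 < self.train_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    """A classifier family plus its (documented-default) hyperparameters."""

    family: str
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


@dataclass(frozen=True)
class Configuration:
    """One (context, model, similarity measure, encoding) combination."""

    context_label: str
    model: ModelConfig
    measure: SimilarityMeasure
    encoding: str

    @property
    def family(self) -> str:
        return self.model.family

    @property
    def name(self) -> str:
        return f"{self.family}+{self.measure.name}+{self.encoding}"


# ---------------------------------------------------------------------------
# Splitting and balancing
# ---------------------------------------------------------------------------

def split_dataset(
    db: SequentialDatabase, plan: SplitPlan
) -> tuple[list[str], list[str]]:
    """Patient-level random split into internal and external parts."""
    ids = db.patient_ids
    labels = [db.outcome[p] for p in ids]
    for cls in (DEAD,):
        if labels.count(cls) < 2 or len(labels) - labels.count(cls) < 2:
            raise SplitError("need at least 2 patients in each outcome class")
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(len(ids))
    n_internal = int(round(plan.internal_fraction * len(ids)))
    internal = sorted(ids[i] for i in perm[:n_internal])
    external = sorted(ids[i] for i in perm[n_internal:])
    return internal, external


def balance(
    ids: Sequence[str], outcomes: Mapping[str, str], seed: int
) -> list[str]:
    """Equalize outcome classes by undersampling the majority class.

    The minority class is kept intact; the majority class is subsampled
    uniformly at random.
    """
    dead = sorted(p for p in ids if outcomes[p] == DEAD)
    alive = sorted(p for p in ids if outcomes[p] != DEAD)
    if not dead or not alive:
        raise SplitError("both outcome classes must be present to balance")
    rng = np.random.default_rng(seed)
    if len(dead) < len(alive):
        alive = sorted(rng.choice(alive, size=len(dead), replace=False))
    elif len(alive) < len(dead):
        dead = sorted(rng.choice(dead, size=len(alive), replace=False))
    return sorted(dead + alive)


def _stratified_split(
    ids: Sequence[str], outcomes: Mapping[str, str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Shuffle within each outcome class so both parts keep both classes."""
    rng = np.random.default_rng(seed)
    first: list[str] = []
    second: list[str] = []
    for cls_ids in (
        sorted(p for p in ids if outcomes[p] == DEAD),
        sorted(p for p in ids if outcomes[p] != DEAD),
    ):
        perm = rng.permutation(len(cls_ids))
        k = int(round(fraction * len(cls_ids)))
        first.extend(cls_ids[i] for i in perm[:k])
        second.extend(cls_ids[i] for i in perm[k:])
    return sorted(first), sorted(second)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def compute_similarity_matrix(
    db: SequentialDatabase,
    ids: Sequence[str],
    patterns: ContextPatternSet,
    measure: SimilarityMeasure,
) -> pd.DataFrame:
    """Similarity of each patient's trajectory to each context pattern
    (rows: patients, columns sim_1..sim_k)."""
    pattern_texts = [encode(p) for p in patterns.patterns]
    data = {
        pid: [similarity(encode(db.sequences[pid]), t, measure) for t in pattern_texts]
        for pid in ids
    }
    cols = [f"sim_{i + 1}" for i in range(len(pattern_texts))]
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def assemble_features(
    context: Context,
    sim_matrix: pd.DataFrame,
    db: SequentialDatabase,
    encoding: str = "continuous",
    sim_cfg: SimilarityConfig = SimilarityConfig(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor matrix (sex, age class, similarities) and label vector.

    Sex and age-class indicators are dropped when constant within the
    context (they carry no information there).  Under the discretized
    encoding each similarity column is expanded to three low / medium /
    strong indicator columns.  Labels: 1 = dead.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"encoding must be one of {ENCODINGS}")
    ids = list(sim_matrix.index)
    attrs = {pid: discretize_covariates(db.covariates[pid]) for pid in ids}
    X = pd.DataFrame(index=sim_matrix.index)
    sex_col = [1.0 if attrs[p]["sex"] == "woman" else 0.0 for p in ids]
    age_col = [1.0 if attrs[p]["age_class"] == ">65" else 0.0 for p in ids]
    if len(set(sex_col)) > 1:
        X["sex_woman"] = sex_col
    if len(set(age_col)) > 1:
        X["age_over65"] = age_col
    if encoding == "continuous":
        for col in sim_matrix.columns:
            X[col] = sim_matrix[col]
    else:
        for col in sim_matrix.columns:
            cats = sim_matrix[col].map(lambda v: discretize_similarity(v, sim_cfg))
            for level in ("low", "medium", "strong"):
                X[f"{col}_{level}"] = (cats == level).astype(float)
    y = pd.Series(
        [1 if db.outcome[p] == DEAD else 0 for p in ids], index=sim_matrix.index, name="dead"
    )
    return X, y


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class Scorer:
    """A fitted classifier exposing death probabilities and hard calls."""

    estimator: object
    columns: tuple[str, ...]
    scaler: StandardScaler | None = None

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        M = X.reindex(columns=self.columns).to_numpy(dtype=float)
        if self.scaler is not None:
            M = self.scaler.transform(M)
        return M

    def predict_death_probability(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.estimator.predict_proba(self._matrix(X))
        idx = list(self.estimator.classes_).index(1)
        return proba[:, idx]

    def predict_label(self, X: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_death_probability(X) >= threshold).astype(int)


def _make_estimator(model: ModelConfig, n_features: int, seed: int, encoding: str):
    p = model.params
    fam = model.family
    if fam == "NB":
        # Gaussian for continuous features; the discretized encoding is
        # one-hot, where per-indicator Bernoulli factors realize a
        # categorical naive Bayes.
        return GaussianNB() if encoding == "continuous" else BernoulliNB()
    if fam == "KNN":
        return KNeighborsClassifier(n_neighbors=p.get("k", 5))
    if fam == "Tree":
        return DecisionTreeClassifier(random_state=seed, **{k: v for k, v in p.items() if k != "prune"})
    if fam == "LR":
        # unpenalized logistic regression
        return LogisticRegression(C=np.inf, max_iter=p.get("max_iter", 2000))
    if fam == "SVM":
        # Radial kernel; decision scores mapped to probabilities by
        # Platt-style sigmoid calibration.
        svc = SVC(kernel=p.get("kernel", "rbf"), C=p.get("C", 1.0), random_state=seed)
        return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False, cv=3)
    if fam == "ANN":
        hidden = p.get("hidden", max(3, n_features))
        return MLPClassifier(
            hidden_layer_sizes=(hidden,),
            alpha=p.get("alpha", 1e-2),
            max_iter=p.get("max_iter", 600),
            random_state=seed,
        )
    raise AssertionError(fam)


def train_classifier(
    X: pd.DataFrame, y: Sequence[int], model: ModelConfig, seed: int = 0,
    encoding: str = "continuous",
) -> Scorer:
    """Fit one classifier family; returns a probability-capable scorer.

    Regression trees are pruned by cost-complexity: candidate alphas
    come from the pruning path and the winner is chosen by internal
    3-fold cross-validated accuracy.  KNN, SVM and ANN see standardized
    features.  Failures surface as :class:`TrainingError` so the
    configuration can be flagged and excluded from selection.
    """
    yarr = np.asarray(y, dtype=int)
    if len(np.unique(yarr)) < 2:
        raise TrainingError("labels are constant; nothing to learn")
    if X.isna().to_numpy().any():
        raise TrainingError("missing values in features")
    M = X.to_numpy(dtype=float)
    scaler = None
    if model.family in ("KNN", "SVM", "ANN"):
        scaler = StandardScaler().fit(M)
        M = scaler.transform(M)
    est = _make_estimator(model, X.shape[1], seed, encoding)
    try:
        if model.family == "Tree" and model.params.get("prune", True):
            est = _prune_tree(est, M, yarr, seed)
        est.fit(M, yarr)
    except Exception as exc:  # noqa: BLE001 - flagged, not fatal
        raise TrainingError(f"{model.family} failed to train: {exc}") from exc
    return Scorer(est, tuple(X.columns), scaler)


def _prune_tree(est: DecisionTreeClassifier, M, y, seed: int) -> DecisionTreeClassifier:
    path = est.cost_complexity_pruning_path(M, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0, None))
    if len(alphas) > 8:
        alphas = alphas[np.linspace(0, len(alphas) - 1, 8).astype(int)]
    # drop the degenerate root-only alpha at the end of the path
    alphas = alphas[:-1] if len(alphas) > 1 else alphas
    best_alpha, best_score = 0.0, -np.inf
    n_splits = min(3, int(np.min(np.bincount(y))))
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for alpha in alphas:
            cand = DecisionTreeClassifier(random_state=seed, ccp_alpha=float(alpha))
            score = float(np.mean(cross_val_score(cand, M, y, cv=cv)))
            if score > best_score:
                best_alpha, best_score = float(alpha), score
    return DecisionTreeClassifier(random_state=seed, ccp_alpha=best_alpha)


def enumerate_configurations(
    families: Sequence[str] = FAMILIES,
    measures: Sequence[SimilarityMeasure] | None = None,
    encodings: Sequence[str] = ENCODINGS,
    contexts: Sequence[Context | str] = ("general",),
) -> list[Configuration]:
    """Full cross-product of model family x measure x encoding per context."""
    if measures is None:
        measures = all_measures()
    if not (families and measures and encodings and contexts):
        raise ValueError("families, measures, encodings and contexts must be non-empty")
    labels = [c.label if isinstance(c, Context) else c for c in contexts]
    return [
        Configuration(label, ModelConfig(fam), meas, enc)
        for label in labels
        for fam in families
        for meas in measures
        for enc in encodings
    ]


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything needed to run the pipeline end to end."""

    mining: MiningConfig = field(default_factory=lambda: MiningConfig(min_support=0.01))
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    families: tuple[str, ...] = FAMILIES
    measures: tuple[SimilarityMeasure, ...] = tuple(all_measures())
    encodings: tuple[str, ...] = ENCODINGS
    n_repeats: int = 5
    min_patients: int = 20
    min_events_per_class: int = 5
    criteria: tuple[tuple[str, int], ...] = evaluation.DEFAULT_CRITERIA
    #: optional restriction to specific context labels (None = all included)
    context_labels: tuple[str, ...] | None = None

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load from YAML/JSON: split fractions, seeds, repeats, model
        hyperparameters, measure and encoding lists."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "mining" in raw:
            kwargs["mining"] = MiningConfig(**raw["mining"])
        if "similarity" in raw:
            kwargs["similarity"] = SimilarityConfig(**raw["similarity"])
        if "split" in raw:
            kwargs["split"] = SplitPlan(**raw["split"])
        if "measures" in raw:
            kwargs["measures"] = tuple(SimilarityMeasure(m) for m in raw["measures"])
        for key in ("families", "encodings"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("n_repeats", "min_patients", "min_events_per_class"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class ContextResult:
    """All configuration records plus the nominated best for one context."""

    context: Context
    patterns: ContextPatternSet
    records: list[evaluation.EvaluationRecord]
    front: list[evaluation.EvaluationRecord]
    selected: evaluation.EvaluationRecord | None
    failed: list[tuple[Configuration, str]]


@dataclass
class StudyResult:
    contexts: list[Context]
    internal_ids: list[str]
    external_ids: list[str]
    per_context: list[ContextResult]

    @property
    def records(self) -> list[evaluation.EvaluationRecord]:
        return [r for cr in self.per_context for r in cr.records]

    @property
    def selected(self) -> list[evaluation.EvaluationRecord]:
        return [cr.selected for cr in self.per_context if cr.selected is not None]


def run_study(
    db: SequentialDatabase, cfg: StudyConfig, seed: int = 0
) -> StudyResult:
    """Mine, featurize, train, select and externally validate, per context.

    Patterns are mined from internal patients only so the external
    split stays untouched end to end.  Configurations that fail to
    train are flagged and excluded from selection.
    """
    db.validate()
    rng = np.random.default_rng(seed)
    plan = replace(cfg.split, seed=int(rng.integers(2**31)))
    internal_ids, external_ids = split_dataset(db, plan)
    internal_set = set(internal_ids)

    contexts = enumerate_contexts(db, cfg.min_patients, cfg.min_events_per_class)
    included = [c for c in contexts if not c.excluded]
    if cfg.context_labels is not None:
        included = [c for c in included if c.label in cfg.context_labels]
    per_context: list[ContextResult] = []
    for ctx in included:
        ctx_internal = sorted(ctx.member_ids & internal_set)
        ctx_external = sorted(ctx.member_ids - internal_set)
        int_outcomes = [db.outcome[p] for p in ctx_internal]
        if int_outcomes.count(DEAD) < 2 or int_outcomes.count(DEAD) > len(int_outcomes) - 2:
            logger.info("context %r: too few internal events, skipped", ctx.label)
            continue
        mining_ctx = Context(
            constraints=dict(ctx.constraints),
            member_ids=frozenset(ctx_internal),
            label=ctx.label,
        )
        patterns = mine_contextual_maximal(db, [mining_ctx], cfg.mining)[0]
        if not patterns.patterns:
            logger.info("context %r: no frequent patterns, skipped", ctx.label)
            continue

        all_ids = ctx_internal + ctx_external
        features: dict[tuple[str, str], tuple[pd.DataFrame, pd.Series]] = {}
        for measure in cfg.measures:
            sims = compute_similarity_matrix(db, all_ids, patterns, measure)
            for enc in cfg.encodings:
                features[(measure.name, enc)] = assemble_features(
                    ctx, sims, db, encoding=enc, sim_cfg=cfg.similarity
                )

        records: list[evaluation.EvaluationRecord] = []
        failed: list[tuple[Configuration, str]] = []
        configs = [
            Configuration(ctx.label, ModelConfig(fam), meas, enc)
            for fam in cfg.families
            for meas in cfg.measures
            for enc in cfg.encodings
        ]
        round_seeds = [int(rng.integers(2**31)) for _ in range(cfg.n_repeats)]
        for config in configs:
            X, y = features[(config.measure.name, config.encoding)]
            try:
                rec = _evaluate_internal(
                    config, X, y, ctx_internal, db, plan, round_seeds, cfg
                )
            except (TrainingError, SplitError) as exc:
                logger.warning("configuration %s in %r flagged: %s", config.name, ctx.label, exc)
                failed.append((config, str(exc)))
                continue
            records.append(rec)

        front = evaluation.pareto_select(records, cfg.criteria) if records else []
        selected = evaluation.nominate_best(records, cfg.criteria) if records else None
        if selected is not None:
            X, y = features[(selected.configuration.measure.name, selected.configuration.encoding)]
            fit_ids = balance(ctx_internal, db.outcome, seed=round_seeds[0])
            scorer = train_classifier(
                X.loc[fit_ids], y.loc[fit_ids], selected.configuration.model,
                seed=round_seeds[0], encoding=selected.configuration.encoding,
            )
            if ctx_external:
                ext_aurc, ext_brier = evaluation.validate_external(
                    scorer, X.loc[ctx_external], y.loc[ctx_external]
                )
                selected.external_aurc = ext_aurc
                selected.brier = ext_brier
        per_context.append(
            ContextResult(ctx, patterns, records, front, selected, failed)
        )
    return StudyResult(contexts, internal_ids, external_ids, per_context)


def _evaluate_internal(
    config: Configuration,
    X: pd.DataFrame,
    y: pd.Series,
    ctx_internal: list[str],
    db: SequentialDatabase,
    plan: SplitPlan,
    round_seeds: Sequence[int],
    cfg: StudyConfig,
) -> evaluation.EvaluationRecord:
    """Repeated stratified holdout on the internal part; metrics averaged."""
    metric_rows: list[evaluation.MetricSet] = []
    aurcs: list[float] = []
    predicted: list[float] = []
    observed: list[float] = []
    for rseed in round_seeds:
        train_ids, test_ids = _stratified_split(
            ctx_internal, db.outcome, plan.train_fraction, rseed
        )
        train_ids = balance(train_ids, db.outcome, seed=rseed + 1)
        test_ids = balance(test_ids, db.outcome, seed=rseed + 2)
        scorer = train_classifier(
            X.loc[train_ids], y.loc[train_ids], config.model,
            seed=rseed, encoding=config.encoding,
        )
        probs = scorer.predict_death_probability(X.loc[test_ids])
        hard = (probs >= 0.5).astype(int)
        y_test = y.loc[test_ids].to_numpy()
        metric_rows.append(evaluation.confusion_metrics(y_test, hard))
        aurcs.append(evaluation.aurc(y_test, probs))
        predicted.append(float(hard.sum()))
        observed.append(float(y_test.sum()))
    mean = lambda xs: float(np.mean(xs))  # noqa: E731
    metrics = evaluation.MetricSet(
        accuracy=mean([m.accuracy for m in metric_rows]),
        sensitivity=mean([m.sensitivity for m in metric_rows]),
        specificity=mean([m.specificity for m in metric_rows]),
        error_rate=mean([m.error_rate for m in metric_rows]),
        precision=mean([m.precision for m in metric_rows]),
        f_measure=mean([m.f_measure for m in metric_rows]),
        aurc=mean(aurcs),
    )
    return evaluation.EvaluationRecord(
        configuration=config,
        metrics=metrics,
        observed_deaths=mean(observed),
        predicted_deaths=mean(predicted),
    )
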
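"""Splitting, balancing, feature assembly and classifier training."""

import numpy as np
import pandas as pd
import pytest

from caremine.evaluation import aurc
from caremine.pattern_mining import MiningConfig
from caremine.prediction import (
    ENCODINGS,
    FAMILIES,
    Configuration,
    ModelConfig,
    SplitPlan,
    SplitError,
    StudyConfig,
    TrainingError,
    assemble_features,
    balance,
    compute_similarity_matrix,
    enumerate_configurations,
    run_study,
    split_dataset,
    train_classifier,
)
from caremine.similarity import SimilarityMeasure
from caremine.synthetic_data import GeneratorConfig, generate_cohort
from caremine.trajectory_db import Context


def _toy_features(n=60, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = rng.normal(size=n)
    if separable:
        x = x + 10 * y
    X = pd.DataFrame({"f1": x, "f2": rng.normal(size=n)},
                     index=[f"p{i}" for i in range(n)])
    return X, pd.Series(y, index=X.index)


class TestSplit:
    def test_two_thirds_split_is_disjoint_and_exhaustive(self):
        db, _ = generate_cohort(GeneratorConfig(n_patients=100, seed=0))
        plan = SplitPlan(internal_fraction=2 / 3, seed=5)
        internal, external = split_dataset(db, plan)
        assert len(internal) == 67 and len(external) == 33
        assert set(internal) & set(external) == set()
        assert set(internal) | set(external) == set(db.sequences)

    def test_same_seed_reproduces_split(self):
        db, _ = generate_cohort(GeneratorConfig(n_patients=80, seed=1))
        plan = SplitPlan(seed=9)
        assert split_dataset(db, plan) == split_dataset(db, plan)

    def test_study_proportions(self):
        db, _ = generate_cohort(GeneratorConfig(n_patients=4871, seed=2))
        internal, external = split_dataset(db, SplitPlan(seed=0))
        assert len(internal) == 3245 and len(external) == 1626

    def test_split_requires_both_classes(self):
        db, _ = generate_cohort(GeneratorConfig(n_patients=30, seed=3))
        for pid in db.outcome:
            db.outcome[pid] = "alive"
        with pytest.raises(SplitError):
            split_dataset(db, SplitPlan())


class TestBalance:
    def test_majority_undersampled_to_minority_count(self):
        outcomes = {f"a{i}": "alive" for i in range(100)}
        outcomes.update({f"d{i}": "dead" for i in range(20)})
        ids = balance(sorted(outcomes), outcomes, seed=0)
        labels = [outcomes[p] for p in ids]
        assert labels.count("dead") == labels.count("alive") == 20

    def test_minority_class_kept_intact(self):
        outcomes = {f"a{i}": "alive" for i in range(50)}
        outcomes.update({f"d{i}": "dead" for i in range(10)})
        ids = balance(sorted(outcomes), outcomes, seed=1)
        assert {p for p in ids if outcomes[p] == "dead"} == {f"d{i}" for i in range(10)}

    def test_already_balanced_input_unchanged(self):
        outcomes = {"a": "alive", "b": "dead"}
        assert balance(["a", "b"], outcomes, seed=2) == ["a", "b"]

    def test_deterministic_under_seed(self):
        outcomes = {f"a{i}": "alive" for i in range(40)} | {f"d{i}": "dead" for i in range(8)}
        ids = sorted(outcomes)
        assert balance(ids, outcomes, seed=7) == balance(ids, outcomes, seed=7)

    def test_single_class_rejected(self):
        with pytest.raises(SplitError):
            balance(["a", "b"], {"a": "alive", "b": "alive"}, seed=0)


@pytest.fixture(scope="module")
def cohort():
    db, _ = generate_cohort(GeneratorConfig(n_patients=300, seed=4))
    from caremine.pattern_mining import mine_contextual_maximal
    from caremine.trajectory_db import enumerate_contexts

    contexts = enumerate_contexts(db)
    general = next(c for c in contexts if c.is_general)
    leaf = next(
        c for c in contexts
        if c.constraints == {"sex": "man", "age_class": ">65", "stay_class": ">5"}
    )
    [ps] = mine_contextual_maximal(db, [general], MiningConfig(min_support=0.3))
    return db, general, leaf, ps


class TestFeatures:

    def test_general_context_keeps_sex_and_age_columns(self, cohort):
        db, general, _, ps = cohort
        sims = compute_similarity_matrix(
            db, sorted(general.member_ids), ps, SimilarityMeasure("levenshtein")
        )
        X, y = assemble_features(general, sims, db, encoding="continuous")
        k = len(ps.patterns)
        assert list(X.columns[:2]) == ["sex_woman", "age_over65"]
        assert X.shape[1] == 2 + k
        assert set(y.unique()) <= {0, 1}

    def test_fully_constrained_context_drops_constant_columns(self, cohort):
        db, _, leaf, ps = cohort
        sims = compute_similarity_matrix(
            db, sorted(leaf.member_ids), ps, SimilarityMeasure("levenshtein")
        )
        X, _ = assemble_features(leaf, sims, db, encoding="continuous")
        assert "sex_woman" not in X.columns and "age_over65" not in X.columns
        assert X.shape[1] == len(ps.patterns)

    def test_discretized_encoding_one_hot_expands(self, cohort):
        db, general, _, ps = cohort
        sims = compute_similarity_matrix(
            db, sorted(general.member_ids), ps, SimilarityMeasure("levenshtein")
        )
        X, _ = assemble_features(general, sims, db, encoding="discretized")
        k = len(ps.patterns)
        assert X.shape[1] == 2 + 3 * k
        level_cols = [c for c in X.columns if c.startswith("sim_")]
        assert set(X[level_cols].to_numpy().ravel()) <= {0.0, 1.0}
        # exactly one level active per similarity per patient
        for i in range(1, k + 1):
            block = X[[f"sim_{i}_low", f"sim_{i}_medium", f"sim_{i}_strong"]]
            assert (block.sum(axis=1) == 1).all()


class TestTrainClassifier:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_probabilities_valid_on_separable_data(self, family):
        X, y = _toy_features(separable=True)
        scorer = train_classifier(X, y, ModelConfig(family), seed=0)
        p = scorer.predict_death_probability(X)
        assert np.all((0 <= p) & (p <= 1)) and np.all(np.isfinite(p))

    @pytest.mark.parametrize("family", ["SVM", "LR"])
    def test_separable_case_reaches_full_training_accuracy(self, family):
        X, y = _toy_features(separable=True)
        scorer = train_classifier(X, y, ModelConfig(family), seed=0)
        assert (scorer.predict_label(X) == y.to_numpy()).mean() == 1.0

    def test_null_features_give_chance_level_aurc(self):
        X, y = _toy_features(n=400, seed=8, separable=False)
        train = X.index[:260]
        test = X.index[260:]
        scorer = train_classifier(X.loc[train], y.loc[train], ModelConfig("LR"), seed=0)
        a = aurc(y.loc[test].to_numpy(), scorer.predict_death_probability(X.loc[test]))
        assert 0.4 <= a <= 0.6

    def test_deterministic_predictions_under_seed(self):
        X, y = _toy_features(seed=9)
        for family in FAMILIES:
            s1 = train_classifier(X, y, ModelConfig(family), seed=3)
            s2 = train_classifier(X, y, ModelConfig(family), seed=3)
            assert np.allclose(
                s1.predict_death_probability(X), s2.predict_death_probability(X)
            )

    def test_constant_labels_flagged(self):
        X, y = _toy_features()
        with pytest.raises(TrainingError):
            train_classifier(X, pd.Series(np.zeros(len(X)), index=X.index), ModelConfig("LR"))


class TestConfigurations:
    def test_full_cross_product_is_108(self):
        assert len(enumerate_configurations()) == 108

    @pytest.mark.parametrize(
        "nf, nm, ne, expected", [(1, 1, 1, 1), (2, 3, 2, 12)]
    )
    def test_partial_products(self, nf, nm, ne, expected):
        from caremine.similarity import all_measures

        cfgs = enumerate_configurations(
            FAMILIES[:nf], all_measures()[:nm], ENCODINGS[:ne], ["general"]
        )
        assert len(cfgs) == expected

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configurations(families=())


class TestStudy:
    def test_no_leakage_and_records_complete(self):
        db, _ = generate_cohort(GeneratorConfig.strong_signal(n_patients=600, seed=0))
        cfg = StudyConfig(
            mining=MiningConfig(min_support=0.3),
            families=("LR", "NB"),
            measures=(SimilarityMeasure("levenshtein"),),
            encodings=("continuous",),
            n_repeats=2,
            context_labels=("general",),
        )
        result = run_study(db, cfg, seed=1)
        assert set(result.internal_ids) & set(result.external_ids) == set()
        assert set(result.internal_ids) | set(result.external_ids) == set(db.sequences)
        [cr] = result.per_context
        assert len(cr.records) == 2  # 2 families x 1 measure x 1 encoding
        for rec in cr.records:
            assert rec.metrics.aurc is not None and np.isfinite(rec.metrics.aurc)
            assert rec.metrics.error_rate == pytest.approx(1 - rec.metrics.accuracy)
        assert cr.selected is not None
        assert cr.selected.external_aurc is not None
        assert 0 <= cr.selected.brier <= 1

    def test_config_file_round_trip(self, tmp_path):
        f = tmp_path / "study.yaml"
        f.write_text(
            "mining: {min_support: 0.05}\n"
            "split: {internal_fraction: 0.7, train_fraction: 0.6, seed: 3}\n"
            "families: [SVM, LR]\n"
            "measures: [levenshtein, jaro]\n"
            "encodings: [continuous]\n"
            "n_repeats: 4\n"
        )
        cfg = StudyConfig.from_file(f)
        assert cfg.mining.min_support == 0.05
        assert cfg.split.internal_fraction == 0.7
        assert cfg.families == ("SVM", "LR")
        assert [m.name for m in cfg.measures] == ["levenshtein", "jaro"]
        assert cfg.n_repeats == 4
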
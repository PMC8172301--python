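"""Contextual mining: embedding, support, PrefixSpan growth, maximality."""

import numpy as np
import pytest

from caremine.pattern_mining import (
    ContextPatternSet,
    MiningConfig,
    ResourceLimitError,
    SequentialPattern,
    UndefinedSupportError,
    filter_maximal,
    is_subsequence,
    mine_contextual_maximal,
    mine_frequent,
    support,
)
from caremine.trajectory_db import Context, EventSequence, SequentialDatabase
from conftest import micro_db_as_database, random_micro_database
from reference import embeds, enumerate_frequent

P = SequentialPattern.of


def _db(*seqs) -> tuple[SequentialDatabase, Context]:
    db = SequentialDatabase(
        sequences={
            f"Q{i}": EventSequence(f"Q{i}", tuple(frozenset(s) for s in seq))
            for i, seq in enumerate(seqs)
        }
    )
    return db, Context({}, frozenset(db.sequences), label="general")


class TestEmbedding:
    def test_worked_example_pattern_embeds_in_p1(self, table1_db):
        assert is_subsequence(P("R07", "I20"), table1_db.sequences["P01"])

    def test_empty_pattern_embeds_vacuously(self, table1_db):
        assert is_subsequence(SequentialPattern(()), table1_db.sequences["P14"])

    def test_order_violation_fails(self):
        seq = EventSequence("x", (frozenset({"R07"}), frozenset({"I20"})))
        assert not is_subsequence(P("I20", "R07"), seq)

    def test_itemset_containment_required(self):
        seq = EventSequence("x", (frozenset({"R07"}), frozenset({"I20"})))
        assert not is_subsequence(P({"R07", "I20"}), seq)
        seq2 = EventSequence("y", (frozenset({"R07", "I20", "I25"}),))
        assert is_subsequence(P({"R07", "I20"}), seq2)


class TestSupport:
    def test_worked_example_supports(self, table1_db, over65_context, mid_age_context):
        pat = P("R07", "I20")
        assert support(pat, table1_db, mid_age_context) == pytest.approx(1 / 6)
        # the printed table yields 7 of 8 supporters in the older class
        assert support(pat, table1_db, over65_context) == pytest.approx(7 / 8)

    def test_empty_pattern_has_full_support(self, table1_db, over65_context):
        assert support(SequentialPattern(()), table1_db, over65_context) == 1.0

    def test_unknown_code_has_zero_support(self, table1_db, over65_context):
        assert support(P("Z99"), table1_db, over65_context) == 0.0

    def test_empty_context_is_an_error(self, table1_db):
        with pytest.raises(UndefinedSupportError):
            support(P("R07"), table1_db, Context({}, frozenset(), label="void"))

    def test_support_invariant_under_patient_relabelling(self, table1_db, over65_context):
        perm = {pid: f"Z{i}" for i, pid in enumerate(sorted(table1_db.sequences))}
        db2 = SequentialDatabase(
            sequences={
                perm[p]: EventSequence(perm[p], s.itemsets)
                for p, s in table1_db.sequences.items()
            }
        )
        ctx2 = Context({}, frozenset(perm[p] for p in over65_context.member_ids))
        assert support(P("R07", "I20"), db2, ctx2) == support(
            P("R07", "I20"), table1_db, over65_context
        )


class TestMineFrequent:
    def test_frequency_decision_at_two_thirds(self, table1_db, over65_context, mid_age_context):
        cfg = MiningConfig(min_support=2 / 3)
        older = dict(mine_frequent(table1_db, over65_context, cfg))
        younger = dict(mine_frequent(table1_db, mid_age_context, cfg))
        assert P("R07", "I20") in older
        assert P("R07", "I20") not in younger
        assert all(s >= 2 / 3 for s in older.values())

    def test_identical_singleton_sequences_at_full_support(self):
        db, ctx = _db(*[[{"I21"}]] * 4)
        assert mine_frequent(db, ctx, MiningConfig(min_support=1.0)) == [
            (P("I21"), 1.0)
        ]

    def test_exact_rational_threshold_at_boundary(self):
        # 2 of 3 supporters at minsup 2/3: kept despite float rounding
        db, ctx = _db([{"A"}], [{"A"}], [{"B"}])
        mined = dict(mine_frequent(db, ctx, MiningConfig(min_support=2 / 3)))
        assert P("A") in mined and P("B") not in mined

    @pytest.mark.parametrize("multi_item", [False, True])
    def test_matches_exhaustive_enumeration(self, multi_item):
        rng = np.random.default_rng(42)
        cfg = MiningConfig(
            min_support=0.3,
            max_pattern_length=4 if not multi_item else 3,
            max_itemset_size=2 if multi_item else 1,
        )
        for _ in range(30):
            seqs = random_micro_database(rng, multi_item=multi_item)
            db, ctx = micro_db_as_database(seqs)
            mined = {
                tuple(p.itemsets): s for p, s in mine_frequent(db, ctx, cfg)
            }
            need = cfg.count_needed(len(seqs))
            oracle = enumerate_frequent(
                seqs, need, cfg.max_pattern_length, cfg.max_itemset_size
            )
            assert mined.keys() == oracle.keys()
            for pat, count in oracle.items():
                assert mined[pat] == pytest.approx(count / len(seqs))

    def test_prefix_support_anti_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seqs = random_micro_database(rng)
            db, ctx = micro_db_as_database(seqs)
            mined = dict(mine_frequent(db, ctx, MiningConfig(min_support=0.2)))
            for pat, s in mined.items():
                if len(pat.itemsets) > 1:
                    prefix = SequentialPattern(pat.itemsets[:-1])
                    assert mined[prefix] >= s

    def test_pattern_cap_raises_resource_error(self, table1_db, over65_context):
        cfg = MiningConfig(min_support=0.01, max_patterns=3)
        with pytest.raises(ResourceLimitError, match="raise min_support"):
            mine_frequent(table1_db, over65_context, cfg)


class TestMaximalFilter:
    def test_printed_six_pattern_set_reduces_to_three(self):
        F = [
            P("I20"),
            P("I20", "I21", "I25"),
            P("I20", "I21"),
            P("I21", "I25"),
            P("I21", "I20"),
            P("I20", "I21", "I24"),
        ]
        assert filter_maximal(F) == [
            P("I20", "I21", "I25"),
            P("I21", "I20"),
            P("I20", "I21", "I24"),
        ]

    def test_singleton_is_kept(self):
        assert filter_maximal([P("I20")]) == [P("I20")]

    def test_nested_chain_keeps_only_longest(self):
        chain = [P("A"), P("A", "B"), P("A", "B", "C")]
        assert filter_maximal(chain) == [P("A", "B", "C")]

    def test_idempotent_and_pairwise_incomparable(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seqs = random_micro_database(rng)
            db, ctx = micro_db_as_database(seqs)
            mined = [p for p, _ in mine_frequent(db, ctx, MiningConfig(min_support=0.3))]
            maximal = filter_maximal(mined)
            assert filter_maximal(maximal) == maximal
            for i, p in enumerate(maximal):
                for j, q in enumerate(maximal):
                    if i != j:
                        assert not embeds(p.itemsets, q.itemsets)


class TestContextualMaximal:
    def test_single_context_equals_composition(self, table1_db, over65_context):
        cfg = MiningConfig(min_support=2 / 3)
        [result] = mine_contextual_maximal(table1_db, [over65_context], cfg)
        expected = filter_maximal(
            [p for p, _ in mine_frequent(table1_db, over65_context, cfg)]
        )
        assert set(result.patterns) == set(expected)
        assert all(s >= 2 / 3 for s in result.supports)

    def test_canonical_ordering_support_desc_then_text(self, table1_db, over65_context):
        cfg = MiningConfig(min_support=0.25)
        [result] = mine_contextual_maximal(table1_db, [over65_context], cfg)
        keys = [(-s, p.to_text()) for p, s in zip(result.patterns, result.supports)]
        assert keys == sorted(keys)

    def test_context_specific_pattern_reported_only_where_frequent(self):
        rng = np.random.default_rng(5)
        fillers = ["X1", "X2", "X3", "X4", "X5"]
        planted = ("A", "B")

        def make_seq(plant: bool):
            codes = list(rng.choice(fillers, size=5))
            if plant:
                i, j = sorted(rng.choice(5, size=2, replace=False))
                codes[i], codes[j] = planted
            return [{c} for c in codes]

        seqs_a = [make_seq(rng.random() < 0.4) for _ in range(300)]
        seqs_b = [make_seq(rng.random() < 0.02) for _ in range(300)]
        db = SequentialDatabase(
            sequences={
                f"A{i}": EventSequence(f"A{i}", tuple(frozenset(s) for s in seq))
                for i, seq in enumerate(seqs_a)
            }
            | {
                f"B{i}": EventSequence(f"B{i}", tuple(frozenset(s) for s in seq))
                for i, seq in enumerate(seqs_b)
            }
        )
        ctx_a = Context({"sex": "man"}, frozenset(k for k in db.sequences if k[0] == "A"))
        ctx_b = Context({"sex": "woman"}, frozenset(k for k in db.sequences if k[0] == "B"))
        cfg = MiningConfig(min_support=0.1)
        res_a, res_b = mine_contextual_maximal(db, [ctx_a, ctx_b], cfg)
        target = P("A", "B")
        in_a = any(is_subsequence(target, p) for p in res_a.patterns)
        in_b = any(is_subsequence(target, p) for p in res_b.patterns)
        assert in_a and not in_b
        # planted support recovered within 3 binomial standard errors
        s = support(target, db, ctx_a)
        assert abs(s - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / 300)


class TestPatternText:
    def test_round_trip(self):
        pat = SequentialPattern((("I20", "I25"), ("R07",)))
        assert pat.to_text() == "<(I20 I25)(R07)>"
        assert SequentialPattern.from_text(pat.to_text()) == pat

    def test_json_export_carries_supports(self, table1_db, over65_context):
        cfg = MiningConfig(min_support=2 / 3)
        [result] = mine_contextual_maximal(table1_db, [over65_context], cfg)
        import json

        payload = json.loads(result.to_json())
        assert payload["context"] == over65_context.label
        assert all(e["support"] >= 2 / 3 for e in payload["patterns"])
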
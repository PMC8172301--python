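"""Shared fixtures: the 14-patient worked-example database and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from caremine.trajectory_db import (
    Context,
    PatientCovariates,
    SequentialDatabase,
    StayRecord,
    build_trajectories,
)

# The printed example database: 14 patients, codes per month (1=Jan..4=Apr).
TABLE1_ROWS: dict[str, list[tuple[int, str]]] = {
    "P01": [(2, "R07"), (2, "I21"), (4, "I20")],
    "P02": [(1, "R07"), (1, "I50"), (3, "I20")],
    "P03": [(1, "R07"), (2, "R07"), (4, "I20")],
    "P04": [(1, "I25"), (2, "R07"), (4, "I20"), (4, "I25")],
    "P05": [(1, "I21"), (2, "R07"), (2, "I25"), (3, "I20"), (3, "I25"), (3, "I21")],
    "P06": [(2, "I20"), (4, "R07")],
    "P07": [(2, "R07"), (3, "I20"), (4, "R07")],
    "P08": [(1, "I21"), (2, "R07"), (4, "I20"), (4, "I25")],
    "P09": [(2, "R07"), (3, "R07"), (4, "I20"), (4, "I21")],
    "P10": [(3, "I20"), (3, "I25"), (3, "I21")],
    "P11": [(3, "I20"), (3, "I21"), (4, "R07")],
    "P12": [(1, "I50"), (2, "I20"), (2, "I25"), (2, "I21"), (4, "R07")],
    "P13": [(2, "I20"), (2, "I21"), (2, "I50")],
    "P14": [(1, "I20"), (3, "R07"), (4, "I50")],
}

#: (sex, age class) per patient as printed; >65 mapped to age 70, 45-65 to 50.
TABLE1_COVARIATES: dict[str, tuple[str, float]] = {
    **{f"P{i:02d}": ("man", 70.0) for i in range(1, 6)},
    **{f"P{i:02d}": ("woman", 70.0) for i in range(6, 9)},
    **{f"P{i:02d}": ("man", 50.0) for i in range(9, 12)},
    **{f"P{i:02d}": ("woman", 50.0) for i in range(12, 15)},
}


def table1_records() -> list[StayRecord]:
    return [
        StayRecord(pid, idx, code)
        for pid, rows in TABLE1_ROWS.items()
        for idx, code in rows
    ]


@pytest.fixture(scope="session")
def table1_db() -> SequentialDatabase:
    db = build_trajectories(table1_records())
    for pid, seq in db.sequences.items():
        sex, age = TABLE1_COVARIATES[pid]
        db.covariates[pid] = PatientCovariates(sex, age, n_stays=len(seq))
        # arbitrary fixed outcomes so outcome-aware code paths run
        db.outcome[pid] = "dead" if pid in {"P05", "P08", "P12"} else "alive"
    db.validate()
    return db


@pytest.fixture(scope="session")
def over65_context(table1_db) -> Context:
    ids = frozenset(p for p, (_, age) in TABLE1_COVARIATES.items() if age > 65)
    return Context({"age_class": ">65"}, ids)


@pytest.fixture(scope="session")
def mid_age_context(table1_db) -> Context:
    ids = frozenset(p for p, (_, age) in TABLE1_COVARIATES.items() if age <= 65)
    return Context({"age_class": "45-65"}, ids)


def random_micro_database(rng: np.random.Generator, multi_item: bool = False):
    """A tiny random sequence database for oracle-equivalence checks."""
    n_patients = int(rng.integers(3, 13))
    vocab = [f"C{i}" for i in range(int(rng.integers(2, 6)))]
    sequences = []
    for _ in range(n_patients):
        length = int(rng.integers(1, 6))
        if multi_item:
            seq = tuple(
                frozenset(rng.choice(vocab, size=int(rng.integers(1, 3)), replace=False))
                for _ in range(length)
            )
        else:
            seq = tuple(frozenset({str(rng.choice(vocab))}) for _ in range(length))
        sequences.append(seq)
    return sequences


def micro_db_as_database(sequences) -> tuple[SequentialDatabase, Context]:
    from caremine.trajectory_db import EventSequence

    db = SequentialDatabase(
        sequences={
            f"M{i}": EventSequence(f"M{i}", seq) for i, seq in enumerate(sequences)
        }
    )
    ctx = Context({}, frozenset(db.sequences), label="general")
    return db, ctx
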
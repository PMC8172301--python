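"""Stay-level records, patient trajectories and the context hierarchy.

A *trajectory* is a patient's time-ordered sequence of coded hospital
stays (ICD-10 diagnosis codes or DRG stay-group codes).  Stays sharing
the same temporal rank (e.g. the same month) form one *itemset*; a
trajectory is an ordered list of itemsets.  Patients are stratified
into *contexts* — conjunctions of covariate classes over sex, age class
(45-65 vs >65 years) and number-of-stays class (<=5 vs >5) — and every
later stage of the pipeline (mining, featurization, modelling) operates
per context.

The temporal rank is an abstract non-negative integer ``order_index``
supplied by the caller (a month number, a stay rank ...): the module is
deliberately agnostic about calendar parsing.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("caremine")

#: Recognized code systems for stay records.
CODE_SYSTEMS = ("ICD10", "DRG")

#: Covariate class labels.
SEXES = ("man", "woman")
AGE_CLASSES = ("45-65", ">65")
STAY_CLASSES = ("<=5", ">5")

ALIVE = "alive"
DEAD = "dead"

DEFAULT_AGE_CUT = 65.0
DEFAULT_STAY_CUT = 5


class InputError(ValueError):
    """Raised for unreadable or malformed input files."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration values (unknown code system ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StayRecord:
    """One coded event of one hospital stay.

    ``order_index`` is the temporal rank of the stay within the patient;
    several records may share a rank (same stay / same month), in which
    case their codes form one itemset of the trajectory.
    """

    patient_id: str
    order_index: int
    code: str
    code_system: str = "ICD10"

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("StayRecord.code must be non-empty")
        if self.code_system not in CODE_SYSTEMS:
            raise ConfigurationError(
                f"unknown code_system {self.code_system!r}; expected one of {CODE_SYSTEMS}"
            )
        if self.order_index < 0:
            raise ValueError("order_index must be non-negative")


@dataclass(frozen=True)
class PatientCovariates:
    """Sex, age in years and number of retained stays for one patient."""

    sex: str
    age_years: float
    n_stays: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if self.n_stays <= 0:
            raise ValueError("n_stays must be positive")


@dataclass(frozen=True)
class EventSequence:
    """A patient's ordered list of itemsets of event codes (trajectory T_P)."""

    patient_id: str
    itemsets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.itemsets:
            raise ValueError("EventSequence needs at least one itemset")
        if any(len(s) == 0 for s in self.itemsets):
            raise ValueError("empty itemsets are not allowed")

    @property
    def n_events(self) -> int:
        return sum(len(s) for s in self.itemsets)

    def __len__(self) -> int:
        return len(self.itemsets)


@dataclass
class Context:
    """A sub-population defined by a conjunction of covariate constraints.

    ``constraints`` is a partial assignment over ``sex``, ``age_class``
    and ``stay_class``; the empty assignment is the *general* context
    containing every patient.  ``excluded`` flags contexts screened out
    for insufficient size or insufficient events per outcome class; they
    remain listed so that reports can show the full hierarchy.
    """

    constraints: dict[str, str]
    member_ids: frozenset[str]
    label: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = context_label(self.constraints)

    @property
    def is_general(self) -> bool:
        return not self.constraints

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class SequentialDatabase:
    """Per-patient trajectories, covariates and the binary outcome.

    The three maps share an identical key set once fully assembled;
    :func:`build_trajectories` produces a sequences-only database to
    which covariates and outcomes are attached afterwards.
    """

    sequences: dict[str, EventSequence]
    covariates: dict[str, PatientCovariates] = field(default_factory=dict)
    outcome: dict[str, str] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def validate(self) -> None:
        keys = set(self.sequences)
        if self.covariates and set(self.covariates) != keys:
            raise ValueError("covariate keys differ from sequence keys")
        if self.outcome and set(self.outcome) != keys:
            raise ValueError("outcome keys differ from sequence keys")
        bad = {o for o in self.outcome.values()} - {ALIVE, DEAD}
        if bad:
            raise ValueError(f"unknown outcome labels: {bad}")

    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for seq in self.sequences.values():
            for itemset in seq.itemsets:
                vocab |= itemset
        return vocab

    def subset(self, ids: Iterable[str]) -> "SequentialDatabase":
        ids = set(ids)
        return SequentialDatabase(
            sequences={p: s for p, s in self.sequences.items() if p in ids},
            covariates={p: c for p, c in self.covariates.items() if p in ids},
            outcome={p: o for p, o in self.outcome.items() if p in ids},
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

#: Expected header of the stay-record CSV interface.
CSV_COLUMNS = ("patient_id", "order_index", "code", "code_system", "sex", "age", "outcome")


def load_stay_records(path, dialect: str = "excel") -> list[StayRecord]:
    """Read stay records from a delimited text file.

    The file must carry at least ``patient_id``, ``order_index`` and
    ``code`` columns (the full cohort interface adds ``code_system``,
    ``sex``, ``age`` and ``outcome``; see :func:`load_cohort_csv`).
    Rows missing a patient id or a code are rejected and counted.
    """
    records: list[StayRecord] = []
    n_rejected = 0
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, dialect=dialect)
            if reader.fieldnames is None:
                raise InputError(f"{path}: empty file")
            for row in reader:
                pid = (row.get("patient_id") or "").strip()
                code = (row.get("code") or "").strip()
                if not pid or not code:
                    n_rejected += 1
                    continue
                records.append(
                    StayRecord(
                        patient_id=pid,
                        order_index=int(row["order_index"]),
                        code=code,
                        code_system=(row.get("code_system") or "ICD10").strip(),
                    )
                )
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if n_rejected:
        logger.warning("load_stay_records: rejected %d rows missing patient_id or code", n_rejected)
    return records


def load_cohort_csv(path) -> "SequentialDatabase":
    """Load the full cohort CSV (stays + covariates + outcome) into a database.

    One row per code per stay, header ``patient_id,order_index,code,
    code_system,sex,age,outcome``; sex/age/outcome must be constant
    within a patient.
    """
    records: list[StayRecord] = []
    sex: dict[str, str] = {}
    age: dict[str, float] = {}
    outcome: dict[str, str] = {}
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise InputError(f"{path}: missing columns {sorted(missing)}")
            n_rejected = 0
            for row in reader:
                pid = (row.get("patient_id") or "").strip()
                code = (row.get("code") or "").strip()
                if not pid or not code:
                    n_rejected += 1
                    continue
                records.append(
                    StayRecord(pid, int(row["order_index"]), code, row["code_system"].strip())
                )
                sex[pid] = row["sex"].strip()
                age[pid] = float(row["age"])
                outcome[pid] = row["outcome"].strip()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if n_rejected:
        logger.warning("load_cohort_csv: rejected %d rows missing patient_id or code", n_rejected)
    db = build_trajectories(records)
    for pid, seq in db.sequences.items():
        db.covariates[pid] = PatientCovariates(sex[pid], age[pid], n_stays=len(seq))
        db.outcome[pid] = outcome[pid]
    db.validate()
    return db


def write_cohort_csv(db: SequentialDatabase, path) -> None:
    """Serialize a database to the stay-record CSV interface (round-trips)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for pid in db.patient_ids:
            cov = db.covariates[pid]
            out = db.outcome[pid]
            for idx, itemset in enumerate(db.sequences[pid].itemsets):
                for code in sorted(itemset):
                    writer.writerow([pid, idx, code, "ICD10", cov.sex, cov.age_years, out])


# ---------------------------------------------------------------------------
# Filtering and trajectory construction
# ---------------------------------------------------------------------------

def filter_relevant_stays(
    records: Sequence[StayRecord], keep_prefixes: Sequence[str]
) -> list[StayRecord]:
    """Keep only records whose code starts with one of ``keep_prefixes``.

    Mirrors the cohort-construction step that drops stays unrelated to
    the condition of interest.  Relative order within each patient is
    preserved; a patient losing every stay simply disappears from the
    output (logged, not an error).
    """
    if not keep_prefixes:
        raise ConfigurationError("keep_prefixes must be non-empty")
    prefixes = tuple(keep_prefixes)
    kept = [r for r in records if r.code.startswith(prefixes)]
    before = {r.patient_id for r in records}
    after = {r.patient_id for r in kept}
    dropped = before - after
    if dropped:
        logger.info("filter_relevant_stays: %d patients lost all stays and were dropped", len(dropped))
    return kept


def build_trajectories(records: Sequence[StayRecord]) -> SequentialDatabase:
    """Group records into per-patient ordered itemset sequences.

    Codes sharing a patient's ``order_index`` form one itemset; itemsets
    are ordered by ``order_index``.  Duplicate (patient, order_index,
    code) triples are deduplicated with a warning.  The result contains
    sequences only; covariates/outcomes are attached by the caller.
    """
    by_patient: dict[str, dict[int, set[str]]] = {}
    seen: set[tuple[str, int, str]] = set()
    n_dup = 0
    for rec in records:
        key = (rec.patient_id, rec.order_index, rec.code)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        by_patient.setdefault(rec.patient_id, {}).setdefault(rec.order_index, set()).add(rec.code)
    if n_dup:
        logger.warning("build_trajectories: deduplicated %d repeated (patient, index, code) rows", n_dup)
    sequences = {
        pid: EventSequence(
            pid, tuple(frozenset(stays[idx]) for idx in sorted(stays))
        )
        for pid, stays in by_patient.items()
    }
    return SequentialDatabase(sequences=sequences)


# ---------------------------------------------------------------------------
# Covariate discretization and contexts
# ---------------------------------------------------------------------------

def discretize_covariates(
    cov: PatientCovariates,
    age_cut: float = DEFAULT_AGE_CUT,
    stay_cut: int = DEFAULT_STAY_CUT,
    age_min: float = 45.0,
) -> dict[str, str]:
    """Map covariates to the three context attributes.

    Boundaries are left-inclusive on the lower class, matching the class
    labels "45-65 years" and "<=5 stays": age exactly at the cut falls
    in ``45-65`` and a stay count exactly at the cut falls in ``<=5``.
    An age at or below the inclusion minimum (45 years) raises, as such
    patients are excluded upstream.
    """
    if cov.age_years <= age_min:
        logger.info("excluding patient aged %.1f (inclusion minimum %g)", cov.age_years, age_min)
        raise ValueError(f"age {cov.age_years} at or below inclusion minimum {age_min}")
    return {
        "sex": cov.sex,
        "age_class": "45-65" if cov.age_years <= age_cut else ">65",
        "stay_class": "<=5" if cov.n_stays <= stay_cut else ">5",
    }


_LABEL_PARTS = {
    "sex": lambda v: v,
    "age_class": lambda v: f"{v} years",
    "stay_class": lambda v: f"{v} stays",
}
_ATTR_ORDER = ("sex", "age_class", "stay_class")


def context_label(constraints: Mapping[str, str]) -> str:
    """Canonical human-readable context name, e.g. ``man and >65 years and <=5 stays``."""
    if not constraints:
        return "general"
    return " and ".join(_LABEL_PARTS[a](constraints[a]) for a in _ATTR_ORDER if a in constraints)


def enumerate_contexts(
    db: SequentialDatabase,
    min_patients: int = 0,
    min_events_per_class: int = 0,
    age_cut: float = DEFAULT_AGE_CUT,
    stay_cut: int = DEFAULT_STAY_CUT,
) -> list[Context]:
    """Enumerate the full context hierarchy over sex x age class x stay class.

    Each of the three attributes is either fixed to one of its two
    values or left free, giving 3 x 3 x 3 = 27 candidate contexts
    including the general one.  Contexts with fewer than ``min_patients``
    members, or fewer than ``min_events_per_class`` patients in either
    outcome class, are flagged ``excluded`` but still listed.
    """
    attrs = {
        pid: discretize_covariates(cov, age_cut=age_cut, stay_cut=stay_cut)
        for pid, cov in db.covariates.items()
    }
    domains = {"sex": SEXES, "age_class": AGE_CLASSES, "stay_class": STAY_CLASSES}
    contexts: list[Context] = []
    for sex in (None, *domains["sex"]):
        for age in (None, *domains["age_class"]):
            for stay in (None, *domains["stay_class"]):
                constraints = {
                    k: v
                    for k, v in (("sex", sex), ("age_class", age), ("stay_class", stay))
                    if v is not None
                }
                members = frozenset(
                    pid
                    for pid, a in attrs.items()
                    if all(a[k] == v for k, v in constraints.items())
                )
                ctx = Context(constraints=constraints, member_ids=members)
                if len(members) < min_patients:
                    ctx.excluded = True
                    ctx.exclusion_reason = f"fewer than {min_patients} patients"
                elif min_events_per_class and db.outcome:
                    counts = {ALIVE: 0, DEAD: 0}
                    for pid in members:
                        counts[db.outcome[pid]] += 1
                    if min(counts.values()) < min_events_per_class:
                        ctx.excluded = True
                        ctx.exclusion_reason = (
                            f"fewer than {min_events_per_class} events in a class"
                        )
                contexts.append(ctx)
    return contexts


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def database_to_json(db: SequentialDatabase) -> str:
    payload = {
        "sequences": {
            pid: [sorted(s) for s in seq.itemsets] for pid, seq in db.sequences.items()
        },
        "covariates": {
            pid: {"sex": c.sex, "age_years": c.age_years, "n_stays": c.n_stays}
            for pid, c in db.covariates.items()
        },
        "outcome": dict(db.outcome),
    }
    return json.dumps(payload, sort_keys=True)


def database_from_json(text: str) -> SequentialDatabase:
    payload = json.loads(text)
    return SequentialDatabase(
        sequences={
            pid: EventSequence(pid, tuple(frozenset(s) for s in itemsets))
            for pid, itemsets in payload["sequences"].items()
        },
        covariates={
            pid: PatientCovariates(c["sex"], c["age_years"], c["n_stays"])
            for pid, c in payload["covariates"].items()
        },
        outcome=dict(payload["outcome"]),
    )


def contexts_to_json(contexts: Sequence[Context]) -> str:
    return json.dumps(
        [
            {
                "constraints": ctx.constraints,
                "label": ctx.label,
                "members": sorted(ctx.member_ids),
                "excluded": ctx.excluded,
                "exclusion_reason": ctx.exclusion_reason,
            }
            for ctx in contexts
        ],
        sort_keys=True,
    )
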
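"""Discrimination metrics, Pareto model selection and validation reports.

Internal validation scores every (model, similarity, encoding)
configuration with accuracy, sensitivity, specificity, error rate,
precision, F-measure and the area under the ROC curve (AURC); the
best compromise is selected by maximal-vector (Pareto skyline)
computation over a configurable criterion list — by default AURC and
F-measure maximized and error rate minimized.  External validation
reports AURC (discrimination) and the Brier score (overall accuracy)
on the untouched hold-out split, kept unbalanced as observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger("caremine")

#: Default selection criteria: (metric, orientation), +1 maximize, -1 minimize.
DEFAULT_CRITERIA: tuple[tuple[str, int], ...] = (
    ("aurc", +1),
    ("f_measure", +1),
    ("error_rate", -1),
)


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AURC)."""


@dataclass
class MetricSet:
    """The seven internal-validation criteria for one configuration."""

    accuracy: float
    sensitivity: float
    specificity: float
    error_rate: float
    precision: float
    f_measure: float
    aurc: float | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | None]:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy",
                "sensitivity",
                "specificity",
                "error_rate",
                "precision",
                "f_measure",
                "aurc",
            )
        }


@dataclass
class EvaluationRecord:
    """Internal (and optionally external) results for one configuration."""

    configuration: Any
    metrics: MetricSet
    observed_deaths: float | None = None
    predicted_deaths: float | None = None
    external_aurc: float | None = None
    brier: float | None = None


def _metric(record, name: str) -> float:
    if isinstance(record, Mapping):
        return float(record[name])
    if hasattr(record, "metrics") and hasattr(record.metrics, name):
        v = getattr(record.metrics, name)
        if v is not None:
            return float(v)
    if hasattr(record, name):
        return float(getattr(record, name))
    raise KeyError(f"record has no metric {name!r}")


def _record_name(record) -> str:
    if isinstance(record, Mapping):
        return str(record.get("name", ""))
    cfg = getattr(record, "configuration", None)
    return str(getattr(cfg, "name", cfg))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_metrics(labels: Sequence[int], predictions: Sequence[int]) -> MetricSet:
    """Accuracy, sensitivity, specificity, error rate, precision, F-measure.

    Labels and hard predictions are binary with 1 = death.  A ratio
    with zero denominator is reported as 0 and its name listed in
    ``undefined``.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if not set(np.unique(y)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}:
        raise ValueError("labels and predictions must be binary 0/1")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    n = len(y)
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, n, "accuracy")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if precision + sensitivity == 0:
        undefined.append("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        error_rate=1.0 - accuracy,
        precision=precision,
        f_measure=f_measure,
        undefined=tuple(undefined),
    )


def aurc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (trapezoid; ties get half credit).

    Equals the Mann-Whitney statistic (concordant + 0.5 tied pairs) /
    (positives x negatives).  Raises if only one class is present.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AURC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def brier(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Mean squared difference between predicted probability and outcome."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# Pareto (maximal vector) selection
# ---------------------------------------------------------------------------

def _oriented(record, criteria) -> tuple[float, ...]:
    return tuple(sign * _metric(record, name) for name, sign in criteria)


def _dominates(u: tuple[float, ...], v: tuple[float, ...]) -> bool:
    return all(a >= b for a, b in zip(u, v)) and any(a > b for a, b in zip(u, v))


def pareto_select(
    records: Sequence, criteria: Sequence[tuple[str, int]] = DEFAULT_CRITERIA
) -> list:
    """The maximal-vector (skyline) subset of ``records``.

    A record survives iff no other record is at least as good on every
    criterion and strictly better on one.  Records may be
    :class:`EvaluationRecord` instances or plain mappings.
    """
    if not records:
        return []
    vecs = [_oriented(r, criteria) for r in records]
    # Scan in order of decreasing lexicographic goodness: any dominator
    # of a record precedes it, so only kept records need checking.
    order = sorted(range(len(records)), key=lambda i: vecs[i], reverse=True)
    kept: list[int] = []
    for i in order:
        if not any(_dominates(vecs[j], vecs[i]) for j in kept):
            kept.append(i)
    kept.sort()
    return [records[i] for i in kept]


def nominate_best(
    records: Sequence, criteria: Sequence[tuple[str, int]] = DEFAULT_CRITERIA
):
    """A single best record: Pareto front, then lexicographic by the
    criteria in order, then by configuration name for determinism."""
    front = pareto_select(records, criteria)
    if not front:
        return None
    return max(front, key=lambda r: (_oriented(r, criteria), _record_name(r)))


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

def validate_external(scorer, features, labels) -> tuple[float | None, float]:
    """AURC and Brier score of a fitted scorer on the external split.

    The external set is used exactly once, unbalanced, as observed.  If
    it lacks one outcome class the AURC is reported as None (flagged)
    while the Brier score is still computed.
    """
    probs = np.asarray(scorer.predict_death_probability(features), dtype=float)
    y = np.asarray(labels)
    b = brier(y, probs)
    try:
        a = aurc(y, probs)
    except UndefinedMetricError:
        logger.warning("external set lacks a class: AURC undefined")
        a = None
    return a, b


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _ci95(values: np.ndarray) -> tuple[float, float]:
    if len(values) < 2:
        v = float(values[0]) if len(values) else float("nan")
        return v, v
    mean = float(np.mean(values))
    half = 1.96 * float(np.std(values, ddof=1)) / np.sqrt(len(values))
    return mean - half, mean + half


def summarize_by_model_and_family(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Mean AURC, F-measure and error rate (with 95% CI) per
    (model family, similarity family) cell, across contexts and measures."""
    rows = []
    for rec in records:
        cfg = rec.configuration
        rows.append(
            {
                "model": cfg.family,
                "similarity_family": cfg.measure.family,
                "aurc": rec.metrics.aurc,
                "f_measure": rec.metrics.f_measure,
                "error_rate": rec.metrics.error_rate,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for (model, fam), grp in df.groupby(["model", "similarity_family"], sort=True):
        row: dict[str, Any] = {"model": model, "similarity_family": fam}
        for metric in ("aurc", "f_measure", "error_rate"):
            vals = grp[metric].dropna().to_numpy()
            row[f"{metric}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            row[f"{metric}_ci_low"], row[f"{metric}_ci_high"] = _ci95(vals)
        out.append(row)
    return pd.DataFrame(out)


def best_combination_distribution(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Distribution (%) of Pareto-best (model, similarity family)
    combinations across contexts."""
    by_context: dict[str, list[EvaluationRecord]] = {}
    for rec in records:
        by_context.setdefault(rec.configuration.context_label, []).append(rec)
    counts: dict[tuple[str, str], int] = {}
    total = 0
    for ctx_records in by_context.values():
        for rec in pareto_select(ctx_records):
            key = (rec.configuration.measure.family, rec.configuration.family)
            counts[key] = counts.get(key, 0) + 1
            total += 1
    rows = [
        {"similarity_family": fam, "model": model, "percent": 100.0 * c / total}
        for (fam, model), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def rank_model_families(
    records: Sequence[EvaluationRecord],
    criteria: Sequence[tuple[str, int]] = DEFAULT_CRITERIA,
    top: int = 3,
) -> pd.DataFrame:
    """Percentage of contexts in which each model family attains each rank.

    Within a context, each family is represented by its best record
    (Pareto-then-lexicographic rule applied within the family), then
    families are ordered by the same rule.
    """
    by_context: dict[str, list[EvaluationRecord]] = {}
    for rec in records:
        by_context.setdefault(rec.configuration.context_label, []).append(rec)
    families = sorted({r.configuration.family for r in records})
    tally = {rank: {fam: 0 for fam in families} for rank in range(1, top + 1)}
    for ctx_records in by_context.values():
        best_per_family = {}
        for fam in families:
            fam_records = [r for r in ctx_records if r.configuration.family == fam]
            if fam_records:
                best_per_family[fam] = nominate_best(fam_records, criteria)
        ordered = sorted(
            best_per_family.items(),
            key=lambda kv: (_oriented(kv[1], criteria), kv[0]),
            reverse=True,
        )
        for rank, (fam, _) in enumerate(ordered[:top], start=1):
            tally[rank][fam] += 1
    n_ctx = len(by_context)
    rows = []
    for rank in range(1, top + 1):
        row: dict[str, Any] = {"rank": rank}
        for fam in families:
            row[fam] = 100.0 * tally[rank][fam] / n_ctx if n_ctx else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def internal_validation_table(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Per-context AURC, error rate and observed / predicted death counts
    for the selected configurations."""
    return pd.DataFrame(
        [
            {
                "context": r.configuration.context_label,
                "configuration": _record_name(r),
                "aurc": r.metrics.aurc,
                "error_rate": r.metrics.error_rate,
                "observed_deaths": r.observed_deaths,
                "predicted_deaths": r.predicted_deaths,
            }
            for r in records
        ]
    )


def external_validation_table(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Per-context external AURC and Brier score for the selected
    configurations."""
    return pd.DataFrame(
        [
            {
                "context": r.configuration.context_label,
                "configuration": _record_name(r),
                "external_aurc": r.external_aurc,
                "brier": r.brier,
            }
            for r in records
        ]
    )


def plot_external_by_context_size(
    table: pd.DataFrame, context_sizes: Mapping[str, int], path=None
):  # pragma: no cover - optional plotting
    """External AURC and Brier against context size (optional report)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.copy()
    df["size"] = df["context"].map(context_sizes)
    df = df.sort_values("size")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(df["size"], df["external_aurc"], "o-")
    axes[0].set_xlabel("context size")
    axes[0].set_ylabel("external AURC")
    axes[1].plot(df["size"], df["brier"], "o-")
    axes[1].set_xlabel("context size")
    axes[1].set_ylabel("Brier score")
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
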
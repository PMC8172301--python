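"""Token-level string measures between trajectories and patterns.

A trajectory and a sequential pattern are each flattened to a *token
text* — one token per event code, itemsets concatenated in order with
codes sorted within an itemset — and compared with classical string
measures applied over tokens, never over the characters of the
multi-character codes (character-level comparison would conflate code
similarity, e.g. I21 vs I25, with sequence similarity).

Nine measures in three families are provided:

=========  =====================================================
family     measures
=========  =====================================================
edition    longest common substring (lcs), levenshtein, optimal
           string alignment (osa), damerau_levenshtein
qgram      qgram (L1 on q-gram count profiles), jaccard (on
           q-gram sets), cosine (on q-gram count vectors)
heuristic  jaro, jaro_winkler
=========  =====================================================

Distances are normalized to similarities in [0, 1]: the heuristic and
q-gram-set measures are already normalized (similarity = 1 - distance);
edit distances divide by the maximum text length (by the summed length
for lcs); the q-gram L1 distance divides by the total profile mass.
Two empty texts are maximally similar by convention; a text shorter
than q has an empty q-gram profile.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pattern_mining import ContextPatternSet, SequentialPattern
from .trajectory_db import EventSequence

logger = logging.getLogger("caremine")

TokenText = tuple[str, ...]

EDITION = "edition"
QGRAM = "qgram"
HEURISTIC = "heuristic"

_FAMILY = {
    "lcs": EDITION,
    "levenshtein": EDITION,
    "osa": EDITION,
    "damerau_levenshtein": EDITION,
    "qgram": QGRAM,
    "jaccard": QGRAM,
    "cosine": QGRAM,
    "jaro": HEURISTIC,
    "jaro_winkler": HEURISTIC,
}

MEASURE_NAMES = tuple(_FAMILY)


@dataclass(frozen=True)
class SimilarityMeasure:
    """One of the nine text-string measures.

    q applies to the q-gram family (default 2: trajectories are short);
    prefix_weight / max_prefix apply to jaro_winkler (the conventional
    0.1 and 4).
    """

    name: str
    q: int = 2
    prefix_weight: float = 0.1
    max_prefix: int = 4

    def __post_init__(self) -> None:
        if self.name not in _FAMILY:
            raise ValueError(f"unknown measure {self.name!r}; choose from {MEASURE_NAMES}")
        if self.q < 1:
            raise ValueError("q must be >= 1")

    @property
    def family(self) -> str:
        return _FAMILY[self.name]


def all_measures(q: int = 2) -> list[SimilarityMeasure]:
    """The nine measures with shared q-gram order."""
    return [SimilarityMeasure(name, q=q) for name in MEASURE_NAMES]


@dataclass(frozen=True)
class SimilarityConfig:
    """Discretization thresholds and encoding choice for similarity features."""

    low_cut: float = 0.4
    strong_cut: float = 0.6
    encoding: str = "continuous"

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.strong_cut < 1:
            raise ValueError("need 0 < low_cut < strong_cut < 1")
        if self.encoding not in ("continuous", "discretized"):
            raise ValueError("encoding must be 'continuous' or 'discretized'")


@dataclass
class SimilarityVector:
    """Per-patient similarities to a context's k patterns, aligned by index."""

    patient_id: str
    context_label: str
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode(obj: EventSequence | SequentialPattern | Iterable) -> TokenText:
    """Flatten a trajectory or pattern to its token text."""
    if isinstance(obj, EventSequence):
        itemsets: Iterable = obj.itemsets
    elif isinstance(obj, SequentialPattern):
        itemsets = obj.itemsets
    else:
        itemsets = obj
    return tuple(tok for itemset in itemsets for tok in sorted(itemset))


# ---------------------------------------------------------------------------
# Edit-based distances
# ---------------------------------------------------------------------------

def _levenshtein(a: TokenText, b: TokenText) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _osa(a: TokenText, b: TokenText) -> int:
    # Optimal string alignment: adjacent transposition, no element reuse.
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = a[i - 1] != b[j - 1]
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


def _damerau_levenshtein(a: TokenText, b: TokenText) -> int:
    # Unrestricted transpositions (Lowrance–Wagner).
    la, lb = len(a), len(b)
    inf = la + lb
    da: dict[str, int] = {}
    d = [[inf] * (lb + 2) for _ in range(la + 2)]
    for i in range(la + 1):
        d[i + 1][1] = i
    for j in range(lb + 1):
        d[1][j + 1] = j
    for i in range(1, la + 1):
        db_ = 0
        for j in range(1, lb + 1):
            i1 = da.get(b[j - 1], 0)
            j1 = db_
            if a[i - 1] == b[j - 1]:
                cost = 0
                db_ = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,
                d[i + 1][j] + 1,
                d[i][j + 1] + 1,
                d[i1][j1] + (i - i1 - 1) + 1 + (j - j1 - 1),
            )
        da[a[i - 1]] = i
    return d[la + 1][lb + 1]


def _lcstr_len(a: TokenText, b: TokenText) -> int:
    # Longest common *contiguous* run of tokens.
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            run = prev[j - 1] + 1 if ca == cb else 0
            cur.append(run)
            if run > best:
                best = run
        prev = cur
    return best


# ---------------------------------------------------------------------------
# q-gram family
# ---------------------------------------------------------------------------

def _qgram_profile(t: TokenText, q: int) -> Counter:
    return Counter(tuple(t[i : i + q]) for i in range(len(t) - q + 1))


def _qgram_l1(a: TokenText, b: TokenText, q: int) -> int:
    pa, pb = _qgram_profile(a, q), _qgram_profile(b, q)
    keys = set(pa) | set(pb)
    return sum(abs(pa[k] - pb[k]) for k in keys)


def _jaccard(a: TokenText, b: TokenText, q: int) -> float:
    sa, sb = set(_qgram_profile(a, q)), set(_qgram_profile(b, q))
    if not sa and not sb:
        return 0.0
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / len(sa | sb)


def _cosine(a: TokenText, b: TokenText, q: int) -> float:
    pa, pb = _qgram_profile(a, q), _qgram_profile(b, q)
    if not pa and not pb:
        return 0.0
    if not pa or not pb:
        return 1.0
    dot = sum(pa[k] * pb[k] for k in pa)
    na = np.sqrt(sum(v * v for v in pa.values()))
    nb = np.sqrt(sum(v * v for v in pb.values()))
    return 1.0 - dot / (na * nb)


# ---------------------------------------------------------------------------
# Heuristic family
# ---------------------------------------------------------------------------

def _jaro_sim(a: TokenText, b: TokenText) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(0, max(len(a), len(b)) // 2 - 1)
    a_flags = [False] * len(a)
    b_flags = [False] * len(b)
    m = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(len(b), i + window + 1)
        for j in range(lo, hi):
            if not b_flags[j] and b[j] == ca:
                a_flags[i] = b_flags[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    a_matched = [ca for i, ca in enumerate(a) if a_flags[i]]
    b_matched = [cb for j, cb in enumerate(b) if b_flags[j]]
    t = sum(x != y for x, y in zip(a_matched, b_matched)) / 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


def _jaro_winkler_sim(a: TokenText, b: TokenText, p: float, max_prefix: int) -> float:
    jaro = _jaro_sim(a, b)
    ell = 0
    for ca, cb in zip(a[:max_prefix], b[:max_prefix]):
        if ca != cb:
            break
        ell += 1
    return jaro + ell * p * (1.0 - jaro)


# ---------------------------------------------------------------------------
# Public distance / similarity API
# ---------------------------------------------------------------------------

def distance(a: TokenText, b: TokenText, m: SimilarityMeasure) -> float:
    """The measure's distance over tokens (0 for identical texts)."""
    a, b = tuple(a), tuple(b)
    if m.name == "levenshtein":
        return float(_levenshtein(a, b))
    if m.name == "osa":
        return float(_osa(a, b))
    if m.name == "damerau_levenshtein":
        return float(_damerau_levenshtein(a, b))
    if m.name == "lcs":
        return float(len(a) + len(b) - 2 * _lcstr_len(a, b))
    if m.name == "qgram":
        return float(_qgram_l1(a, b, m.q))
    if m.name == "jaccard":
        return _jaccard(a, b, m.q)
    if m.name == "cosine":
        return _cosine(a, b, m.q)
    if m.name == "jaro":
        return 1.0 - _jaro_sim(a, b)
    if m.name == "jaro_winkler":
        return 1.0 - _jaro_winkler_sim(a, b, m.prefix_weight, m.max_prefix)
    raise AssertionError(m.name)


def similarity(a: TokenText, b: TokenText, m: SimilarityMeasure) -> float:
    """Normalized similarity in [0, 1]; two empty texts are fully similar."""
    a, b = tuple(a), tuple(b)
    if not a and not b:
        return 1.0
    d = distance(a, b, m)
    if m.name in ("levenshtein", "osa", "damerau_levenshtein"):
        return 1.0 - d / max(len(a), len(b))
    if m.name == "lcs":
        return 1.0 - d / (len(a) + len(b))
    if m.name == "qgram":
        total = sum(_qgram_profile(a, m.q).values()) + sum(_qgram_profile(b, m.q).values())
        return 1.0 if total == 0 else 1.0 - d / total
    # jaccard, cosine, jaro, jaro_winkler are already normalized distances
    return 1.0 - d


def similarity_vector(
    traj: EventSequence, patterns: ContextPatternSet, m: SimilarityMeasure
) -> SimilarityVector:
    """The k-length vector of similarities between a trajectory and a
    context's k maximal patterns."""
    if not patterns.patterns:
        logger.warning(
            "context %r has no patterns: zero-length similarity vector",
            patterns.context.label,
        )
    text = encode(traj)
    values = np.array(
        [similarity(text, encode(p), m) for p in patterns.patterns], dtype=float
    )
    return SimilarityVector(traj.patient_id, patterns.context.label, values)


def discretize_similarity(v: float, cfg: SimilarityConfig = SimilarityConfig()) -> str:
    """Map a similarity to low / medium / strong.

    low: v < low_cut; medium: low_cut <= v < strong_cut; strong:
    v >= strong_cut.
    """
    if not 0 <= v <= 1:
        raise ValueError(f"similarity {v} outside [0, 1]")
    if v < cfg.low_cut:
        return "low"
    if v < cfg.strong_cut:
        return "medium"
    return "strong"
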
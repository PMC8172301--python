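"""Contextual frequent sequential pattern mining and maximal filtering.

Mining is PrefixSpan-style depth-first pattern growth: a frequent
pattern is extended either by appending a new single-item itemset
(*sequence extension*) or by adding a lexicographically larger item to
its last itemset (*itemset extension*), and the database is
pseudo-projected by carrying the set of supporting sequences down the
recursion — anti-monotonicity of support guarantees that a pattern's
supporters are a subset of its prefix's supporters, so each candidate
is counted only against that subset.  Each pattern is generated exactly
once because removing the last added item of any pattern yields a
unique canonical parent.

Support is document frequency: the fraction of a context's patients
whose trajectory embeds the pattern, where embedding means itemset
containment at strictly increasing itemset positions.  The frequency
decision ``support >= min_support`` is taken in exact rational
arithmetic so that thresholds like 2/3 behave correctly at the
boundary.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .trajectory_db import Context, EventSequence, SequentialDatabase

logger = logging.getLogger("caremine")

#: Internal pattern representation: ordered itemsets, each a tuple of
#: lexicographically sorted codes.
Itemsets = tuple[tuple[str, ...], ...]


class ResourceLimitError(RuntimeError):
    """Mining produced more patterns than the configured cap."""


class UndefinedSupportError(ValueError):
    """Support requested in an empty context."""


@dataclass(frozen=True)
class SequentialPattern:
    """An ordered list of itemsets embedded in patient trajectories."""

    itemsets: Itemsets

    def __post_init__(self) -> None:
        for s in self.itemsets:
            if not s:
                raise ValueError("empty itemset in pattern")
            if tuple(sorted(set(s))) != s:
                raise ValueError(f"itemset {s!r} not in canonical sorted, deduplicated order")

    @property
    def length(self) -> int:
        """Total item count across itemsets."""
        return sum(len(s) for s in self.itemsets)

    def to_text(self) -> str:
        """Render as ``<(code ...)(code ...)>``."""
        return "<" + "".join("(" + " ".join(s) + ")" for s in self.itemsets) + ">"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()

    @classmethod
    def from_text(cls, text: str) -> "SequentialPattern":
        """Parse ``<(a b)(c)>`` (whitespace between groups tolerated)."""
        body = text.strip()
        if body.startswith("<") and body.endswith(">"):
            body = body[1:-1]
        groups = re.findall(r"\(([^()]*)\)", body)
        if not groups:
            raise ValueError(f"cannot parse pattern text {text!r}")
        return cls(tuple(tuple(sorted(set(g.split()))) for g in groups))

    @classmethod
    def of(cls, *itemsets: Iterable[str] | str) -> "SequentialPattern":
        """Build from items or iterables: ``SequentialPattern.of("R07", "I20")``."""
        norm = tuple(
            tuple(sorted({s})) if isinstance(s, str) else tuple(sorted(set(s)))
            for s in itemsets
        )
        return cls(norm)


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds.

    min_support : proportion of context patients in (0, 1]; the study
        default is 0.01, low enough to harvest the longest patterns
        short trajectories can support.
    max_pattern_length : cap on total item count, or None.
    max_itemset_size : 1 restricts growth to single-item itemsets (the
        pipeline default; stays are effectively one code per time
        position after filtering); larger values enable full itemset
        growth.
    max_patterns : resource cap; exceeding it aborts with guidance.
    """

    min_support: float | Fraction = 0.01
    max_pattern_length: int | None = None
    max_itemset_size: int = 1
    max_patterns: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < float(self.min_support) <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if self.max_itemset_size < 1:
            raise ValueError("max_itemset_size must be >= 1")

    def count_needed(self, n: int) -> int:
        """Smallest supporter count satisfying support >= min_support, exactly."""
        frac = Fraction(self.min_support).limit_denominator(10**9)
        return max(1, math.ceil(frac * n))


@dataclass
class ContextPatternSet:
    """Maximal frequent patterns of one context, with supports attached."""

    context: Context
    patterns: list[SequentialPattern]
    supports: list[float]

    def __len__(self) -> int:
        return len(self.patterns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "context": self.context.label,
                "patterns": [
                    {"pattern": p.to_text(), "support": s}
                    for p, s in zip(self.patterns, self.supports)
                ],
            }
        )


# ---------------------------------------------------------------------------
# Embedding and support
# ---------------------------------------------------------------------------

def _as_itemsets(obj) -> tuple:
    if isinstance(obj, SequentialPattern):
        return tuple(frozenset(s) for s in obj.itemsets)
    if isinstance(obj, EventSequence):
        return obj.itemsets
    return tuple(frozenset(s) for s in obj)


def is_subsequence(pattern, sequence) -> bool:
    """True iff ``pattern`` embeds in ``sequence``.

    Embedding requires strictly increasing itemset positions j_1 < ... <
    j_m with pattern itemset r contained in sequence itemset j_r; the
    greedy earliest-match scan is exact for this relation.  The empty
    pattern embeds vacuously.
    """
    pat = _as_itemsets(pattern)
    seq = _as_itemsets(sequence)
    j = 0
    for pset in pat:
        while j < len(seq) and not pset <= seq[j]:
            j += 1
        if j == len(seq):
            return False
        j += 1
    return True


def support(pattern, db: SequentialDatabase, context: Context) -> float:
    """Fraction of the context's patients whose trajectory embeds ``pattern``."""
    if not context.member_ids:
        raise UndefinedSupportError(f"context {context.label!r} has no members")
    n_hit = sum(
        1 for pid in context.member_ids if is_subsequence(pattern, db.sequences[pid])
    )
    return n_hit / len(context.member_ids)


# ---------------------------------------------------------------------------
# Frequent mining (PrefixSpan-style growth)
# ---------------------------------------------------------------------------

def mine_frequent(
    db: SequentialDatabase, context: Context, cfg: MiningConfig
) -> list[tuple[SequentialPattern, float]]:
    """All patterns with support >= ``cfg.min_support`` in ``context``.

    Returns (pattern, support) pairs; the empty pattern is not reported.
    """
    if not context.member_ids:
        raise UndefinedSupportError(f"context {context.label!r} has no members")
    ids = sorted(context.member_ids)
    seqs = [db.sequences[pid].itemsets for pid in ids]
    n = len(seqs)
    need = cfg.count_needed(n)

    # Globally frequent single items bound every extension's support.
    item_support: dict[str, list[int]] = {}
    for i, seq in enumerate(seqs):
        for item in set().union(*seq):
            item_support.setdefault(item, []).append(i)
    freq_items = sorted(it for it, sup in item_support.items() if len(sup) >= need)

    results: list[tuple[SequentialPattern, float]] = []

    def grow(pattern: Itemsets, supporters: list[int]) -> None:
        results.append((SequentialPattern(pattern), len(supporters) / n))
        if len(results) > cfg.max_patterns:
            raise ResourceLimitError(
                f"more than {cfg.max_patterns} frequent patterns in context "
                f"{context.label!r}; raise min_support or lower max_pattern_length"
            )
        total = sum(len(s) for s in pattern)
        if cfg.max_pattern_length is not None and total >= cfg.max_pattern_length:
            return
        for item in freq_items:
            # sequence extension: append a new single-item itemset
            cand = pattern + ((item,),)
            sup = [i for i in supporters if is_subsequence(cand, seqs[i])]
            if len(sup) >= need:
                grow(cand, sup)
            # itemset extension: enlarge the last itemset, canonical order
            if (
                cfg.max_itemset_size > 1
                and pattern
                and len(pattern[-1]) < cfg.max_itemset_size
                and item > pattern[-1][-1]
            ):
                cand2 = pattern[:-1] + (pattern[-1] + (item,),)
                sup2 = [i for i in supporters if is_subsequence(cand2, seqs[i])]
                if len(sup2) >= need:
                    grow(cand2, sup2)

    for item in freq_items:
        grow(((item,),), item_support[item])
    return results


def filter_maximal(patterns: Sequence[SequentialPattern]) -> list[SequentialPattern]:
    """Keep exactly the patterns not embedded in any other input pattern.

    Embedding between patterns is the same relation as pattern-in-
    trajectory embedding (subsequence with itemset containment), so the
    survivors are pairwise incomparable and the operation is idempotent.
    """
    out = []
    for i, p in enumerate(patterns):
        absorbed = any(
            i != j and is_subsequence(p, q) for j, q in enumerate(patterns)
        )
        if not absorbed:
            out.append(p)
    return out


def mine_contextual_maximal(
    db: SequentialDatabase, contexts: Sequence[Context], cfg: MiningConfig
) -> list[ContextPatternSet]:
    """Per context: mine frequent patterns, keep the maximal ones.

    Output patterns are ordered canonically — support descending, then
    lexicographically by pattern text — so downstream feature columns
    are reproducible.
    """
    out: list[ContextPatternSet] = []
    for ctx in contexts:
        mined = mine_frequent(db, ctx, cfg)
        supports = {p: s for p, s in mined}
        maximal = filter_maximal([p for p, _ in mined])
        maximal.sort(key=lambda p: (-supports[p], p.to_text()))
        out.append(
            ContextPatternSet(
                context=ctx,
                patterns=maximal,
                supports=[supports[p] for p in maximal],
            )
        )
    return out
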
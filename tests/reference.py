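"""Independent reference implementations used as test oracles.

Everything here is written from the definitions, independently of the
package code paths it checks: exhaustive pattern enumeration instead of
prefix-projection, recursive embedding search instead of the greedy
scan, top-down memoized recurrences (minimizing over *all* restart
pairs for the unrestricted transposition distance) instead of the
package's bottom-up tables, and direct pair counting for AURC and
pairwise dominance for Pareto selection.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache
from itertools import combinations, product
from math import sqrt


# ---------------------------------------------------------------------------
# Sequential patterns
# ---------------------------------------------------------------------------

def embeds(pattern, sequence) -> bool:
    """Recursive search over all increasing position choices."""
    pattern = [set(s) for s in pattern]
    sequence = [set(s) for s in sequence]

    def rec(pi: int, si: int) -> bool:
        if pi == len(pattern):
            return True
        for j in range(si, len(sequence)):
            if pattern[pi] <= sequence[j] and rec(pi + 1, j + 1):
                return True
        return False

    return rec(0, 0)


def enumerate_frequent(
    sequences, min_count: int, max_len: int, max_itemset_size: int = 1
):
    """Every (pattern, count) with count >= min_count, by exhaustive
    enumeration of all candidate patterns up to ``max_len`` items."""
    vocab = sorted({item for seq in sequences for itemset in seq for item in itemset})
    pool = [
        tuple(sorted(c))
        for size in range(1, max_itemset_size + 1)
        for c in combinations(vocab, size)
    ]
    out = {}

    def rec(prefix, total):
        for its in pool:
            if total + len(its) > max_len:
                continue
            pat = prefix + (its,)
            count = sum(embeds(pat, seq) for seq in sequences)
            if count >= min_count:
                out[pat] = count
            rec(pat, total + len(its))

    rec((), 0)
    return out


# ---------------------------------------------------------------------------
# String measures (token-level)
# ---------------------------------------------------------------------------

def ref_levenshtein(a, b) -> int:
    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def ref_osa(a, b) -> int:
    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def ref_damerau(a, b) -> int:
    """Unrestricted transpositions, minimizing over all restart pairs
    (k, l) with a[k] == b[j-1] and b[l] == a[i-1], not just the last
    occurrence."""

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )
        for k in range(i - 1):
            if a[k] != b[j - 1]:
                continue
            for l in range(j - 1):
                if b[l] == a[i - 1]:
                    best = min(best, d(k, l) + (i - k - 2) + (j - l - 2) + 1)
        return best

    return d(len(a), len(b))


def ref_lcstr(a, b) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            best = max(best, k)
    return best


def _grams(t, q):
    return [tuple(t[i : i + q]) for i in range(len(t) - q + 1)]


def ref_qgram(a, b, q=2) -> int:
    ca, cb = Counter(_grams(a, q)), Counter(_grams(b, q))
    return sum(abs(ca[g] - cb[g]) for g in set(ca) | set(cb))


def ref_jaccard(a, b, q=2) -> float:
    sa, sb = set(_grams(a, q)), set(_grams(b, q))
    if not sa and not sb:
        return 0.0
    if not sa or not sb:
        return 1.0
    return 1 - len(sa & sb) / len(sa | sb)


def ref_cosine(a, b, q=2) -> float:
    ca, cb = Counter(_grams(a, q)), Counter(_grams(b, q))
    if not ca and not cb:
        return 0.0
    if not ca or not cb:
        return 1.0
    dot = sum(ca[g] * cb[g] for g in ca if g in cb)
    return 1 - dot / (sqrt(sum(v * v for v in ca.values())) * sqrt(sum(v * v for v in cb.values())))


def ref_jaro(a, b) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    w = max(0, max(len(a), len(b)) // 2 - 1)
    used = [False] * len(b)
    ma, mb = [], []
    for i, x in enumerate(a):
        for j in range(max(0, i - w), min(len(b), i + w + 1)):
            if not used[j] and b[j] == x:
                used[j] = True
                ma.append((i, x))
                break
    mb = [b[j] for j in range(len(b)) if used[j]]
    if not ma:
        return 0.0
    m = len(ma)
    t = sum(x != y for (_, x), y in zip(ma, mb)) / 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


def ref_jaro_winkler(a, b, p=0.1, max_prefix=4) -> float:
    sim = ref_jaro(a, b)
    ell = 0
    for x, y in zip(a, b):
        if x != y or ell == max_prefix:
            break
        ell += 1
    return sim + ell * p * (1 - sim)


# ---------------------------------------------------------------------------
# Metrics and selection
# ---------------------------------------------------------------------------

def ref_aurc(labels, scores) -> float:
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    num = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                num += 1.0
            elif sp == sn:
                num += 0.5
    return num / (len(pos) * len(neg))


def ref_pareto(rows, criteria) -> list:
    """All-pairs dominance check, O(n^2)."""

    def vec(r):
        return tuple(sign * r[name] for name, sign in criteria)

    def dominates(u, v):
        return all(x >= y for x, y in zip(u, v)) and u != v

    vs = [vec(r) for r in rows]
    return [
        r
        for i, r in enumerate(rows)
        if not any(dominates(vs[j], vs[i]) for j in range(len(rows)) if j != i)
    ]
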
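"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the edit
distance is a direct memoized transcription of the recursion, hypergeometric
tails are exact integer/rational summations (or high-precision mpmath for
large counts), AUC is exhaustive pair counting, and modularity maximization
enumerates every set partition.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import mpmath


def osa_brute(a: str, b: str) -> int:
    """Top-down memoized transcription of the OSA recursion."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        opts = []
        if i > 0:
            opts.append(d(i - 1, j) + 1)  # deletion
        if j > 0:
            opts.append(d(i, j - 1) + 1)  # insertion
        if i > 0 and j > 0:
            if a[i - 1] == b[j - 1]:
                opts.append(d(i - 1, j - 1))  # match
            else:
                opts.append(d(i - 1, j - 1) + 1)  # substitution
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            opts.append(d(i - 2, j - 2) + 1)  # transposition
        return min(opts)

    return d(len(a), len(b))


def exact_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact hypergeometric upper tail P(X >= k) as a rational number."""
    if k <= max(0, K + n - N):
        return Fraction(1)
    num = sum(
        math.comb(K, t) * math.comb(N - K, n - t)
        for t in range(k, min(K, n) + 1)
    )
    return Fraction(num, math.comb(N, n))


def exact_tail_suffix(N: int, K: int, n: int) -> list[float]:
    """All tails P(X >= k), k = 0..min(K, n), via integer suffix sums."""
    m = min(K, n)
    terms = [math.comb(K, t) * math.comb(N - K, n - t) for t in range(m + 1)]
    den = math.comb(N, n)
    suffix = [0] * (m + 2)
    for t in range(m, -1, -1):
        suffix[t] = suffix[t + 1] + terms[t]
    return [suffix[t] / den for t in range(m + 1)]


def mp_log_tail(N: int, K: int, n: int, k: int, dps: int = 50) -> float:
    """High-precision ln P(X >= k) for large counts (mpmath).

    The first tail term is evaluated with log-gamma; subsequent terms follow
    the exact pmf ratio recurrence, so the cost is one gamma evaluation plus
    ``min(K, n) - k`` exact multiplications at the working precision.
    """
    with mpmath.workdps(dps):
        def log_comb(a, b):
            return (
                mpmath.loggamma(a + 1)
                - mpmath.loggamma(b + 1)
                - mpmath.loggamma(a - b + 1)
            )

        term = mpmath.e ** (log_comb(K, k) + log_comb(N - K, n - k) - log_comb(N, n))
        total = term
        for t in range(k, min(K, n)):
            # pmf(t+1) / pmf(t), exact rational ratio
            term *= mpmath.mpf((K - t) * (n - t)) / ((t + 1) * (N - K - n + t + 1))
            total += term
        return float(mpmath.log(total))


def auc_pair_counting(pos_scores, neg_scores) -> float:
    """(concordant + 0.5 * ties) / (n_pos * n_neg); higher score = positive."""
    num = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos_scores) * len(neg_scores))


def set_partitions(items):
    """All partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_of(partition, edges, weights=None) -> float:
    """Weighted Newman-Girvan modularity of a node partition."""
    weights = weights or {e: 1.0 for e in edges}
    two_m = 2.0 * sum(weights.values())
    strength: dict = {}
    for (u, v), w in weights.items():
        strength[u] = strength.get(u, 0.0) + w
        strength[v] = strength.get(v, 0.0) + w
    comm = {}
    for ci, group in enumerate(partition):
        for node in group:
            comm[node] = ci
    q = 0.0
    for (u, v), w in weights.items():
        if comm[u] == comm[v]:
            q += 2.0 * w / two_m
    for group in partition:
        s = sum(strength.get(node, 0.0) for node in group)
        q -= (s / two_m) ** 2
    return q


def best_partition_exhaustive(nodes, edges, weights=None):
    """Globally modularity-maximizing partition by full enumeration."""
    best_q, best_p = -math.inf, None
    for part in set_partitions(list(nodes)):
        q = modularity_of(part, edges, weights)
        if q > best_q:
            best_q, best_p = q, part
    return best_p, best_q
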
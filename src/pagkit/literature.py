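"""Literature co-citation enrichment scoring.

Given background citation counts — all disease-related articles ``N``, the
specific disease's articles ``K``, a pathway keyword's articles ``n`` and the
joint disease+keyword count ``k`` — the co-citation score is the negative
natural log of the hypergeometric upper-tail probability of observing at
least ``k`` joint articles, and the odds ratio is
``(k / (K - k)) / ((n - k) / (N - K - n + k))``.  All counts come from a
local table, never a live query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .enrichment import hypergeom_log_upper_tail
from .errors import ArgumentError

__all__ = [
    "CitationCounts",
    "LitScore",
    "pubmed_score",
    "odds_ratio",
    "score_keywords",
    "precision_at_cutoffs",
]


@dataclass(frozen=True)
class CitationCounts:
    """The (N, K, n, k) co-citation contingency counts."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if min(self.N, self.K, self.n, self.k) < 0:
            raise ArgumentError("citation counts must be non-negative")
        if self.k > min(self.n, self.K):
            raise ArgumentError(f"k={self.k} exceeds min(n={self.n}, K={self.K})")
        if self.n > self.N or self.K > self.N:
            raise ArgumentError("n and K must not exceed the background N")


@dataclass(frozen=True)
class LitScore:
    keyword: str
    n: int
    k: int
    odds_ratio: float
    pubmed_score: float


def pubmed_score(c: CitationCounts) -> float:
    """-ln of the hypergeometric upper tail P(X >= k), X ~ Hypergeom(N, K, n).

    Zero when ``k == 0`` (the tail is the whole support); computed in
    log-space so very large counts do not overflow.
    """
    if c.k == 0:
        return 0.0
    return max(0.0, -hypergeom_log_upper_tail(c.N, c.K, c.n, c.k))


def odds_ratio(c: CitationCounts) -> float:
    """Odds ratio of the 2x2 co-citation table.

    Degenerate conventions keep the ranking total: ``k == 0`` gives 0;
    ``k == K`` or ``k == n`` (with ``k > 0``) gives ``+inf``; a non-positive
    ``N - K - n + k`` cell is rejected as a degenerate table.
    """
    rest = c.N - c.K - c.n + c.k
    if rest <= 0:
        raise ArgumentError(
            f"degenerate co-citation table: N-K-n+k = {rest} must be positive"
        )
    if c.k == 0:
        return 0.0
    if c.k == c.K or c.k == c.n:
        return math.inf
    return (c.k / (c.K - c.k)) / ((c.n - c.k) / rest)


def score_keywords(
    counts: Mapping[str, tuple[int, int]], N: int, K: int
) -> list[LitScore]:
    """Score every keyword in a citation-count table against the disease."""
    scores = []
    for kw, (n, k) in counts.items():
        c = CitationCounts(N=N, K=K, n=n, k=k)
        scores.append(
            LitScore(
                keyword=kw,
                n=n,
                k=k,
                odds_ratio=odds_ratio(c),
                pubmed_score=pubmed_score(c),
            )
        )
    return scores


def precision_at_cutoffs(
    scores: Sequence[LitScore],
    k_min: int = 0,
    or_min: float = 0.1,
    score_min: float = 1e-5,
) -> tuple[float, float, float]:
    """Fractions of pathways passing each cutoff (strict ``>`` comparisons).

    Returns precisions under the co-citation count (``k > k_min``), odds
    ratio (``OR > or_min``) and co-citation score (``score > score_min``)
    cutoffs, in that order.
    """
    if not scores:
        raise ArgumentError("precision_at_cutoffs requires a non-empty list")
    total = len(scores)
    p_k = sum(1 for s in scores if s.k > k_min) / total
    p_or = sum(1 for s in scores if s.odds_ratio > or_min) / total
    p_sc = sum(1 for s in scores if s.pubmed_score > score_min) / total
    return (p_k, p_or, p_sc)
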
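"""Hypergeometric over-representation analysis with a rank-aware p-value
adjustment.

The adjustment multiplies each raw p-value ``p0`` by ``m + n_le - 1`` where
``m`` is the number of tests surviving the pre-filters and ``n_le`` is the
number of raw p-values less than or equal to ``p0`` (counting ``p0`` itself);
the product is clamped into (0, 1].  Filtering on overlap size and set
similarity happens *before* the adjustment, so ``m`` is the survivor count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ArgumentError
from .io_formats import PAG

logger = logging.getLogger("pagkit")

__all__ = [
    "GeneSetOverlap",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "hypergeom_log_upper_tail",
    "hypergeom_tail_suffix",
    "similarity_score",
    "adjust_pvalues",
    "enrich",
]


@dataclass(frozen=True)
class GeneSetOverlap:
    """2x2 occupancy of a candidate list vs. one gene set within a universe."""

    pag_id: str
    universe_size: int
    candidate_size: int
    pag_size: int
    overlap_genes: frozenset[str]

    def __post_init__(self) -> None:
        k = len(self.overlap_genes)
        if min(self.universe_size, self.candidate_size, self.pag_size) < 0:
            raise ArgumentError("overlap counts must be non-negative")
        if k > min(self.candidate_size, self.pag_size):
            raise ArgumentError(
                f"overlap {k} exceeds min(candidate, pag) for {self.pag_id!r}"
            )
        if max(self.candidate_size, self.pag_size) > self.universe_size:
            raise ArgumentError("set sizes exceed the universe size")

    @property
    def overlap_count(self) -> int:
        return len(self.overlap_genes)


@dataclass(frozen=True)
class EnrichmentResult:
    pag_id: str
    name: str
    source: str
    overlap: GeneSetOverlap
    p_raw: float
    p_adjusted: float
    similarity_score: float

    @property
    def neg_log2_p(self) -> float:
        return -math.log2(self.p_adjusted)


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_log_upper_tail(
    universe_size: int, pag_size: int, candidate_size: int, overlap: int
) -> float:
    """ln P(X >= overlap), X ~ Hypergeom(universe_size, pag_size, candidate_size).

    Computed by log-space summation of the probability mass from ``overlap``
    to ``min(pag_size, candidate_size)``; exact 0.0 for ``overlap <= 0``.
    Never underflows, so it is safe for extreme citation counts.
    """
    N, K, n, k = universe_size, pag_size, candidate_size, overlap
    if N < 0 or K < 0 or n < 0:
        raise ArgumentError("sizes must be non-negative")
    if K > N or n > N:
        raise ArgumentError(f"set sizes ({K}, {n}) exceed universe size {N}")
    if k > min(K, n):
        raise ArgumentError(f"overlap {k} exceeds min({K}, {n})")
    if k <= max(0, K + n - N):
        return 0.0
    t = np.arange(k, min(K, n) + 1)
    log_pmf = _log_binom(K, t) + _log_binom(N - K, n - t) - _log_binom(N, n)
    return float(min(0.0, logsumexp(log_pmf)))


def hypergeom_upper_tail(
    universe_size: int, pag_size: int, candidate_size: int, overlap: int
) -> float:
    """P(X >= overlap); linear-scale companion of the log-tail above."""
    return math.exp(
        hypergeom_log_upper_tail(universe_size, pag_size, candidate_size, overlap)
    )


def hypergeom_tail_suffix(universe_size: int, pag_size: int, candidate_size: int) -> np.ndarray:
    """Vector of P(X >= k) for k = 0 .. min(pag_size, candidate_size).

    Bulk variant of :func:`hypergeom_upper_tail` sharing its log-space
    formulation; used where many overlap values are tested at once.
    """
    N, K, n = universe_size, pag_size, candidate_size
    if K > N or n > N or min(N, K, n) < 0:
        raise ArgumentError("invalid hypergeometric parameters")
    m = min(K, n)
    t = np.arange(0, m + 1)
    log_pmf = _log_binom(K, t) + _log_binom(N - K, n - t) - _log_binom(N, n)
    # suffix logsumexp: accumulate from the top
    rev = log_pmf[::-1]
    acc = np.logaddexp.accumulate(rev)[::-1]
    tails = np.exp(acc)
    tails[tails > 1.0] = 1.0
    lo = max(0, K + n - N)
    tails[: lo + 1] = 1.0
    return tails


_COMBINERS = {
    "mean": lambda oc, j: (oc + j) / 2.0,
    "min": min,
    "max": max,
}


def similarity_score(overlap: GeneSetOverlap, combiner: str = "mean") -> float:
    """Combined overlap-coefficient / Jaccard similarity in [0, 1].

    ``OC = k / min(|A|, |B|)``, ``J = k / (|A| + |B| - k)``; the default
    combiner is their arithmetic mean (``min`` and ``max`` are alternatives).
    """
    if overlap.candidate_size <= 0 or overlap.pag_size <= 0:
        raise ArgumentError("similarity_score requires non-empty sets")
    try:
        combine = _COMBINERS[combiner]
    except KeyError:
        raise ArgumentError(f"unknown combiner {combiner!r}") from None
    k = overlap.overlap_count
    oc = k / min(overlap.candidate_size, overlap.pag_size)
    j = k / (overlap.candidate_size + overlap.pag_size - k)
    return float(combine(oc, j))


def adjust_pvalues(p_raw: Sequence[float]) -> list[float]:
    """Rank-aware multiple-test adjustment.

    For each raw value ``p0`` among ``m`` tests, the adjusted value is
    ``min(1, p0 * (m + n_le - 1))`` with ``n_le = #{p_i <= p0}`` (inclusive
    of ``p0`` itself, so the multiplier is always >= m >= 1).  Output order
    matches input order; a single test is returned unchanged.
    """
    p = list(p_raw)
    if not p:
        raise ArgumentError("adjust_pvalues requires a non-empty list")
    for v in p:
        if not (0.0 < v <= 1.0):
            raise ArgumentError(f"raw p-value {v} outside (0, 1]")
    arr = np.asarray(p, dtype=float)
    m = len(arr)
    order = np.argsort(arr, kind="stable")
    sorted_p = arr[order]
    # n_le for the sorted array: rightmost index of each tied run, 1-based
    n_le = np.searchsorted(sorted_p, sorted_p, side="right")
    adjusted_sorted = np.minimum(1.0, sorted_p * (m + n_le - 1))
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


def enrich(
    candidates: set[str],
    pags: Sequence[PAG],
    min_overlap: int = 2,
    sim_cutoff: float = 0.0,
    neg_log2p_cutoff: float = 4.32,
    universe: set[str] | None = None,
    combiner: str = "mean",
) -> list[EnrichmentResult]:
    """Over-representation analysis of a candidate list against a collection.

    Pipeline: (1) intersect everything with the universe (the union of all
    collection genes unless one is supplied); (2) drop gene sets whose
    overlap count or similarity score fails the pre-filters; (3) compute raw
    hypergeometric upper-tail p-values for the survivors; (4) apply
    :func:`adjust_pvalues` over those ``m`` survivors; (5) keep results with
    ``-log2(p_adjusted) >= neg_log2p_cutoff``, sorted ascending by adjusted
    p-value with ties broken by ``pag_id``.
    """
    if not pags:
        raise ArgumentError("enrich requires a non-empty PAG collection")
    if universe is None:
        universe = set()
        for pag in pags:
            universe |= pag.genes
    else:
        universe = {g.upper() for g in universe}
    cand = {g.upper() for g in candidates} & universe
    if not cand:
        raise ArgumentError(
            "no candidate genes remain after intersecting with the universe"
        )
    N, n_cand = len(universe), len(cand)

    survivors: list[tuple[PAG, GeneSetOverlap, float]] = []
    for pag in pags:
        pag_genes = pag.genes & universe
        if not pag_genes:
            continue
        ov = GeneSetOverlap(
            pag_id=pag.pag_id,
            universe_size=N,
            candidate_size=n_cand,
            pag_size=len(pag_genes),
            overlap_genes=frozenset(cand & pag_genes),
        )
        if ov.overlap_count < min_overlap:
            continue
        sim = similarity_score(ov, combiner=combiner)
        if sim < sim_cutoff:
            continue
        survivors.append((pag, ov, sim))

    if not survivors:
        logger.warning("no gene set passed the enrichment pre-filters")
        return []

    p_raw = [
        hypergeom_upper_tail(N, ov.pag_size, ov.candidate_size, ov.overlap_count)
        for _, ov, _ in survivors
    ]
    p_adj = adjust_pvalues(p_raw)

    results = [
        EnrichmentResult(
            pag_id=pag.pag_id,
            name=pag.name,
            source=pag.source,
            overlap=ov,
            p_raw=pr,
            p_adjusted=pa,
            similarity_score=sim,
        )
        for (pag, ov, sim), pr, pa in zip(survivors, p_raw, p_adj)
        if -math.log2(pa) >= neg_log2p_cutoff
    ]
    if not results:
        logger.warning("no gene set passed the -log2 adjusted p-value cutoff")
    results.sort(key=lambda r: (r.p_adjusted, r.pag_id))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]):
    """Tabulate enrichment results for TSV export."""
    import pandas as pd

    rows = [
        {
            "pag_id": r.pag_id,
            "name": r.name,
            "source": r.source,
            "overlap_count": r.overlap.overlap_count,
            "overlap_genes": ",".join(sorted(r.overlap.overlap_genes)),
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "similarity_score": r.similarity_score,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pag_id",
            "name",
            "source",
            "overlap_count",
            "overlap_genes",
            "p_raw",
            "p_adjusted",
            "similarity_score",
        ],
    )
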
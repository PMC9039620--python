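"""Cross-tool enrichment-term reconciliation.

Terms are normalized (lower-cased, boilerplate tokens stripped), compared
with the optimal string alignment (OSA) edit distance — the restricted
Damerau-Levenshtein variant that allows single adjacent transpositions but
never edits a transposed substring again — and matched row-wise by highest
similarity.  Matches across all tool pairs form an undirected graph whose
connected components are the consensus concepts feeding the Venn regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ArgumentError

__all__ = [
    "NormalizedTerm",
    "MatchedPair",
    "ConsensusPartition",
    "DEFAULT_STRIP_PATTERNS",
    "osa_distance",
    "string_similarity",
    "normalize_terms",
    "best_matches",
    "consensus_partition",
]

# Species / identifier boilerplate removed during normalization.  Applied
# after lower-casing, so patterns are lower-case.  Fully user-overridable.
DEFAULT_STRIP_PATTERNS: tuple[str, ...] = (
    r"\(\s*human\s*\)",
    r"\(\s*homo sapiens\s*\)",
    r"\bhomo sapiens\b",
    r"\bhuman\b",
    r"\bhsa\d+\b",
    r"\bwp\d+\b",
    r"\br-hsa-\d+\b",
    r"\[[^\]]*\]",
)

_DANGLING = re.compile(r"^[\s\-–:,;]+|[\s\-–:,;]+$")


@dataclass(frozen=True)
class NormalizedTerm:
    raw: str
    normalized: str


@dataclass(frozen=True)
class MatchedPair:
    term_a: NormalizedTerm
    term_b: NormalizedTerm
    similarity: float


@dataclass
class ConsensusPartition:
    """Connected components of the cross-tool match graph.

    Each component is a list of ``(tool_id, NormalizedTerm)`` members plus
    its region — the sorted tuple of distinct tools present.  Region counts
    tally components (not pairs) per region, so a concept spanning all tools
    counts once in the full region.
    """

    components: list[tuple[list[tuple[str, NormalizedTerm]], tuple[str, ...]]]
    region_counts: dict[tuple[str, ...], int]


def osa_distance(a: str, b: str, max_dist: int | None = None) -> int:
    """Optimal string alignment (restricted Damerau-Levenshtein) distance.

    Unit-cost deletions, insertions, substitutions and single adjacent
    transpositions; unlike the unrestricted distance, a transposed pair may
    not be edited again (so ``osa("ca", "abc") == 3``).

    When ``max_dist`` is given and the true distance exceeds it, any value
    greater than ``max_dist`` may be returned (early abandon); exact
    distances at or below ``max_dist`` are always exact.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    if a == b:
        return 0
    # rows i-2, i-1, i of the DP matrix
    prev2 = [0] * (lb + 1)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ai == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        if max_dist is not None and min(cur) > max_dist:
            return max_dist + 1
        prev2, prev = prev, cur
    return prev[lb]


def string_similarity(a: str, b: str) -> float:
    """``1 - osa_distance(a, b) / max(len(a), len(b))``, in [0, 1].

    Two empty strings are defined as identical (similarity 1.0).
    """
    if not a and not b:
        return 1.0
    return 1.0 - osa_distance(a, b) / max(len(a), len(b))


def normalize_term(
    raw: str, strip_patterns: Sequence[str] | None = None
) -> NormalizedTerm:
    """Normalize a single term: lower-case, strip boilerplate, tidy spaces."""
    patterns = DEFAULT_STRIP_PATTERNS if strip_patterns is None else strip_patterns
    s = raw.lower()
    for pat in patterns:
        s = re.sub(pat, " ", s)
    s = re.sub(r"\s+", " ", s).strip()
    s = _DANGLING.sub("", s)
    return NormalizedTerm(raw=raw, normalized=s)


def normalize_terms(
    terms: Iterable[str], strip_patterns: Sequence[str] | None = None
) -> list[NormalizedTerm]:
    """Normalize a tool's term list, collapsing duplicates.

    Terms whose normalized forms coincide (e.g. the same pathway reported by
    two sources) are collapsed to the first occurrence.
    """
    seen: dict[str, NormalizedTerm] = {}
    for raw in terms:
        nt = normalize_term(raw, strip_patterns)
        if nt.normalized not in seen:
            seen[nt.normalized] = nt
    return list(seen.values())


def best_matches(
    set_a: Sequence[NormalizedTerm],
    set_b: Sequence[NormalizedTerm],
    cutoff: float = 0.8,
) -> list[MatchedPair]:
    """Row-wise best matches from ``set_a`` into ``set_b``.

    Each A-term is paired with its single highest-similarity B-term (ties
    resolved to the lexicographically smallest normalized partner); pairs
    below ``cutoff`` are dropped.
    """
    if not set_a or not set_b:
        raise ArgumentError("best_matches requires two non-empty term lists")
    if not (0.0 <= cutoff <= 1.0):
        raise ArgumentError(f"cutoff must be in [0, 1], got {cutoff}")
    pairs: list[MatchedPair] = []
    b_sorted = sorted(set_b, key=lambda t: t.normalized)
    for ta in set_a:
        sa = ta.normalized
        best: NormalizedTerm | None = None
        # current best as an exact rational 1 - best_d/best_len (ties are
        # resolved exactly in integer arithmetic, no float comparisons)
        best_d, best_len = 1, 0  # similarity -inf sentinel
        for tb in b_sorted:
            sb = tb.normalized
            if not sa and not sb:
                d, length = 0, 1  # both empty: similarity 1
            else:
                length = max(len(sa), len(sb))
                # beat current best: need d * best_len < best_d * length
                if best is not None:
                    if abs(len(sa) - len(sb)) * best_len >= best_d * length:
                        continue
                    limit = (best_d * length - 1) // best_len
                    d = osa_distance(sa, sb, max_dist=limit)
                    if d * best_len >= best_d * length:
                        continue
                else:
                    d = osa_distance(sa, sb)
            best, best_d, best_len = tb, d, length
        if best is not None:
            best_sim = 1.0 - best_d / best_len
            if best_sim >= cutoff:
                pairs.append(
                    MatchedPair(term_a=ta, term_b=best, similarity=best_sim)
                )
    return pairs


def consensus_partition(
    lists: Mapping[str, Sequence[NormalizedTerm]], cutoff: float = 0.8
) -> ConsensusPartition:
    """Partition all tools' terms into consensus concepts.

    Nodes are ``(tool, term)``; edges are the union of :func:`best_matches`
    over all ordered tool pairs at ``cutoff`` (the union makes the relation
    symmetric).  Connected components are concepts; a component's region is
    the set of tools it spans.
    """
    tools = sorted(lists)
    if len(tools) < 2:
        raise ArgumentError("consensus_partition requires at least two tools")

    # union-find over (tool, normalized) nodes
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    node_term: dict[tuple[str, str], NormalizedTerm] = {}
    for tool in tools:
        for term in lists[tool]:
            node = (tool, term.normalized)
            parent.setdefault(node, node)
            node_term[node] = term

    for ta in tools:
        for tb in tools:
            if ta == tb or not lists[ta] or not lists[tb]:
                continue
            for pair in best_matches(lists[ta], lists[tb], cutoff):
                union((ta, pair.term_a.normalized), (tb, pair.term_b.normalized))

    groups: dict[tuple[str, str], list[tuple[str, NormalizedTerm]]] = {}
    for node in parent:
        groups.setdefault(find(node), []).append((node[0], node_term[node]))

    components = []
    region_counts: dict[tuple[str, ...], int] = {}
    for members in groups.values():
        members.sort(key=lambda m: (m[0], m[1].normalized))
        region = tuple(sorted({tool for tool, _ in members}))
        components.append((members, region))
        region_counts[region] = region_counts.get(region, 0) + 1
    components.sort(key=lambda c: (-len(c[1]), c[0][0][1].normalized))
    return ConsensusPartition(components=components, region_counts=region_counts)
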
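"""Co-membership (m-type) gene-set network construction, Louvain community
detection, and per-community keyword extraction."""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
from statsmodels.stats.multitest import multipletests

from .enrichment import hypergeom_upper_tail
from .errors import ArgumentError
from .io_formats import PAG

__all__ = [
    "ClusterAssignment",
    "DEFAULT_STOP_WORDS",
    "build_mtype_network",
    "louvain_cluster",
    "cluster_word_frequencies",
]

# Common / uninformative words removed from gene-set names before counting.
DEFAULT_STOP_WORDS: frozenset[str] = frozenset(
    {"pathway", "signaling", "human", "homo", "sapiens", "has", "or", "and"}
)

_PUNCT = string.punctuation.replace("-", "")  # hyphens survive ("il-18")


@dataclass(frozen=True)
class ClusterAssignment:
    membership: dict[str, int]
    modularity: float


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter) if inter else 0.0


def build_mtype_network(
    pags: Sequence[PAG],
    universe_size: int,
    edge_p_cutoff: float = 0.05,
    rule: str = "hypergeom_bh",
    rule_threshold: float | None = None,
) -> nx.Graph:
    """Build the undirected co-membership network over a gene-set collection.

    Default rule: for every unordered pair, the hypergeometric upper-tail
    probability of the shared-gene count is Benjamini-Hochberg adjusted
    across all pairs, and an edge is kept when the adjusted value is at most
    ``edge_p_cutoff``.  Edge weight is always the Jaccard index of the two
    gene sets.  Alternative rules: ``shared_count`` (keep pairs sharing at
    least ``rule_threshold`` genes, default 1) and ``jaccard`` (keep pairs
    with Jaccard at least ``rule_threshold``, default 0.1).
    """
    if len(pags) < 2:
        raise ArgumentError("build_mtype_network requires at least two PAGs")
    biggest = max(len(p.genes) for p in pags)
    if universe_size < biggest:
        raise ArgumentError(
            f"universe_size {universe_size} smaller than largest PAG ({biggest})"
        )
    ids = [p.pag_id for p in pags]
    if len(set(ids)) != len(ids):
        raise ArgumentError("duplicate pag_id in collection")

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    pairs = list(combinations(range(len(pags)), 2))
    shared = [len(pags[i].genes & pags[j].genes) for i, j in pairs]

    if rule == "hypergeom_bh":
        pvals = [
            hypergeom_upper_tail(
                universe_size, len(pags[i].genes), len(pags[j].genes), s
            )
            for (i, j), s in zip(pairs, shared)
        ]
        keep = multipletests(pvals, method="fdr_bh")[1] <= edge_p_cutoff
    elif rule == "shared_count":
        thr = 1 if rule_threshold is None else rule_threshold
        keep = [s >= thr for s in shared]
    elif rule == "jaccard":
        thr = 0.1 if rule_threshold is None else rule_threshold
        keep = [
            _jaccard(pags[i].genes, pags[j].genes) >= thr
            for (i, j) in pairs
        ]
    else:
        raise ArgumentError(f"unknown edge rule {rule!r}")

    for (i, j), s, ok in zip(pairs, shared, keep):
        if ok and s > 0:
            graph.add_edge(
                pags[i].pag_id,
                pags[j].pag_id,
                weight=_jaccard(pags[i].genes, pags[j].genes),
                shared=s,
            )
    return graph


def louvain_cluster(
    net: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> ClusterAssignment:
    """Louvain community detection on the co-membership network.

    Deterministic for a given seed.  Cluster labels are integers starting at
    1, assigned to communities ordered by (size desc, smallest member).  The
    reported modularity is the standard weighted Newman-Girvan modularity of
    the returned membership (0.0 for an edgeless graph, where every node is
    its own singleton community).
    """
    if net.number_of_nodes() == 0:
        raise ArgumentError("louvain_cluster requires a non-empty graph")
    if net.number_of_edges() == 0:
        membership = {n: i + 1 for i, n in enumerate(sorted(net.nodes))}
        return ClusterAssignment(membership=membership, modularity=0.0)
    communities = nx.community.louvain_communities(
        net, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    membership = {}
    for label, comm in enumerate(communities, start=1):
        for node in comm:
            membership[node] = label
    mod = nx.community.modularity(net, communities, weight="weight")
    return ClusterAssignment(membership=membership, modularity=float(mod))


def cluster_word_frequencies(
    pags_by_cluster: Mapping[int, Iterable],
    stop_words: frozenset[str] | set[str] | None = None,
    strip_punct: bool = True,
) -> dict[int, Counter]:
    """Bag-of-words keyword frequencies per cluster.

    Gene-set names (or :class:`PAG` objects) are split on whitespace,
    lower-cased, leading/trailing punctuation stripped from tokens (hyphens
    kept), stop words removed, and occurrences counted.
    """
    stops = DEFAULT_STOP_WORDS if stop_words is None else frozenset(stop_words)
    out: dict[int, Counter] = {}
    for label, members in pags_by_cluster.items():
        counts: Counter = Counter()
        for member in members:
            name = member.name if isinstance(member, PAG) else str(member)
            for token in name.split():
                token = token.lower()
                if strip_punct:
                    token = token.strip(_PUNCT)
                if token and token not in stops:
                    counts[token] += 1
        out[label] = counts
    return out
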
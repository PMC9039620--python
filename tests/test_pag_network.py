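from collections import Counter

import networkx as nx
import numpy as np
import pytest

from _oracles import best_partition_exhaustive, exact_tail
from pagkit.errors import ArgumentError
from pagkit.io_formats import PAG
from pagkit.pag_network import (
    DEFAULT_STOP_WORDS,
    build_mtype_network,
    cluster_word_frequencies,
    louvain_cluster,
)


def _pag(pid, genes, name=None):
    return PAG(pag_id=pid, name=name or pid, source="t", genes=frozenset(genes))


class TestBuildMtypeNetwork:
    def test_disjoint_pags_no_edge(self):
        a = _pag("A", [f"G{i}" for i in range(10)])
        b = _pag("B", [f"H{i}" for i in range(10)])
        net = build_mtype_network([a, b], universe_size=1000)
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"A", "B"}

    def test_identical_pags_strong_edge(self):
        genes = [f"G{i}" for i in range(20)]
        net = build_mtype_network([_pag("A", genes), _pag("B", genes)], 1000)
        assert net.has_edge("A", "B")
        assert net["A"]["B"]["weight"] == 1.0
        # tail from the exact summation oracle is far below the cutoff
        assert float(exact_tail(1000, 20, 20, 20)) < 1e-30

    def test_subset_jaccard_weight(self):
        small = [f"G{i}" for i in range(5)]
        big = [f"G{i}" for i in range(10)]
        net = build_mtype_network(
            [_pag("A", small), _pag("B", big)], 100, edge_p_cutoff=1.0
        )
        assert net["A"]["B"]["weight"] == pytest.approx(0.5)

    def test_universe_smaller_than_pag(self):
        with pytest.raises(ArgumentError):
            build_mtype_network(
                [_pag("A", ["G1", "G2"]), _pag("B", ["G1"])], universe_size=1
            )

    def test_degree_identity(self, bundle):
        net = build_mtype_network(bundle.pags, bundle.spec.universe_size)
        assert sum(d for _, d in net.degree) == 2 * net.number_of_edges()

    def test_edge_set_invariant_to_input_order(self, bundle):
        net1 = build_mtype_network(bundle.pags, bundle.spec.universe_size)
        net2 = build_mtype_network(bundle.pags[::-1], bundle.spec.universe_size)
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))

    def test_alternative_rules(self):
        a = _pag("A", ["G1", "G2", "G3"])
        b = _pag("B", ["G3", "G4", "G5"])
        shared = build_mtype_network([a, b], 100, rule="shared_count")
        assert shared.has_edge("A", "B")
        jac = build_mtype_network([a, b], 100, rule="jaccard", rule_threshold=0.5)
        assert not jac.has_edge("A", "B")
        with pytest.raises(ArgumentError):
            build_mtype_network([a, b], 100, rule="bogus")

    def test_no_self_loops(self, bundle):
        net = build_mtype_network(bundle.pags, bundle.spec.universe_size)
        assert nx.number_of_selfloops(net) == 0


class TestLouvainCluster:
    def test_two_cliques_exhaustive_oracle(self):
        g = nx.Graph()
        left, right = list(range(5)), list(range(5, 10))
        for group in (left, right):
            for i in group:
                for j in group:
                    if i < j:
                        g.add_edge(i, j)
        g.add_edge(4, 5)  # bridge
        expected, best_q = best_partition_exhaustive(
            list(g.nodes), list(g.edges)
        )
        assert sorted(map(sorted, expected)) == [left, right]
        got = louvain_cluster(g, seed=1)
        clusters = {}
        for node, label in got.membership.items():
            clusters.setdefault(label, set()).add(node)
        assert sorted(map(sorted, clusters.values())) == [left, right]
        assert got.modularity == pytest.approx(best_q)

    def test_single_clique_modularity_zero(self):
        g = nx.complete_graph(6)
        got = louvain_cluster(g, seed=0)
        assert len(set(got.membership.values())) == 1
        assert got.modularity == pytest.approx(0.0)

    def test_planted_three_blocks(self):
        from sklearn.metrics import adjusted_rand_score

        truth = [i // 15 for i in range(45)]
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            g = nx.Graph()
            g.add_nodes_from(range(45))
            for i in range(45):
                for j in range(i + 1, 45):
                    p = 0.9 if truth[i] == truth[j] else 0.05
                    if rng.random() < p:
                        g.add_edge(i, j)
            got = louvain_cluster(g, seed=seed)
            pred = [got.membership[i] for i in range(45)]
            aris.append(adjusted_rand_score(truth, pred))
        assert all(a >= 0.9 for a in aris)

    def test_deterministic_given_seed(self, bundle):
        net = build_mtype_network(bundle.pags, bundle.spec.universe_size)
        a = louvain_cluster(net, seed=7)
        b = louvain_cluster(net, seed=7)
        assert a.membership == b.membership
        assert a.modularity == b.modularity

    def test_beats_trivial_partition(self, bundle):
        net = build_mtype_network(bundle.pags, bundle.spec.universe_size)
        if net.number_of_edges() == 0:
            pytest.skip("no edges in fixture network")
        got = louvain_cluster(net, seed=3)
        comms = {}
        for node, label in got.membership.items():
            comms.setdefault(label, set()).add(node)
        one_block = nx.community.modularity(net, [set(net.nodes)], weight="weight")
        assert got.modularity >= one_block

    def test_modularity_in_range(self, bundle):
        net = build_mtype_network(bundle.pags, bundle.spec.universe_size)
        got = louvain_cluster(net, seed=0)
        assert -0.5 <= got.modularity <= 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ArgumentError):
            louvain_cluster(nx.Graph())

    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        got = louvain_cluster(g)
        assert got.modularity == 0.0
        assert len(set(got.membership.values())) == 2


class TestClusterWordFrequencies:
    def test_stop_words_removed(self):
        freqs = cluster_word_frequencies(
            {1: ["il-18 signaling pathway", "il-17 signaling pathway"]}
        )
        assert freqs[1] == Counter({"il-18": 1, "il-17": 1})

    def test_all_stop_words_empty(self):
        freqs = cluster_word_frequencies({1: ["signaling pathway human"]})
        assert freqs[1] == Counter()

    def test_token_conservation(self):
        names = ["Collagen formation pathway", "Collagen binding, formation"]
        freqs = cluster_word_frequencies({1: names})
        total_tokens = sum(len(n.split()) for n in names)
        removed = 2  # two "pathway"-type stop words... counted below
        removed = sum(
            1
            for n in names
            for tok in n.split()
            if tok.lower().strip(".,:;()") in DEFAULT_STOP_WORDS
        )
        assert sum(freqs[1].values()) == total_tokens - removed

    def test_punctuation_stripped_hyphen_kept(self):
        freqs = cluster_word_frequencies({1: ["(il-6) family: signaling."]})
        assert freqs[1] == Counter({"il-6": 1, "family": 1})

    def test_accepts_pag_objects(self):
        pag = _pag("X", ["G1"], name="collagen formation")
        freqs = cluster_word_frequencies({2: [pag]})
        assert freqs[2] == Counter({"collagen": 1, "formation": 1})
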
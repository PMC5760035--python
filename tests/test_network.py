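"""Greedy network construction, Fisher scoring, growth, merging, hubs,
enrichment and direction scores."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from oracles import fisher_right_tail_brute, hypergeom_tail_brute
from tempomir.network import (
    Network,
    build_networks,
    direction_zscore,
    find_hubs,
    gene_set_enrichment,
    grow,
    inject_interaction_edges,
    merge_and_critical_genes,
    network_score,
)


def star_graph():
    g = nx.Graph()
    center = "C00"
    focus_leaves = [f"F{i:02d}" for i in range(10)]
    other_leaves = [f"L{i:02d}" for i in range(40)]
    for leaf in focus_leaves + other_leaves:
        g.add_edge(center, leaf)
    return g, center, focus_leaves


class TestBuildNetworks:
    def test_star_graph_greedy_trace(self):
        g, center, focus_leaves = star_graph()
        nets = build_networks([center] + focus_leaves, g, size=35, n_networks=1)
        assert len(nets) == 1
        net = nets[0]
        # the center (highest degree to focus) seeds the network and every
        # focus leaf is pulled in before any non-focus leaf
        assert center in net.molecules
        assert set(focus_leaves) <= set(net.molecules)
        assert net.focus == {center, *focus_leaves}
        assert len(net.molecules) == 35

    def test_size_cap_connectivity_and_focus_disjointness(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            g = nx.gnp_random_graph(150, 0.05, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(150)})
            dataset = [f"n{i:03d}" for i in rng.choice(150, 40, replace=False)]
            nets = build_networks(dataset, g, size=35, n_networks=3)
            seen_focus = set()
            for net in nets:
                assert len(net.molecules) <= 35
                sub = g.subgraph(net.molecules)
                assert nx.is_connected(sub)
                assert not (net.focus & seen_focus)
                seen_focus |= net.focus
            scores = [n.score for n in nets]
            assert scores == sorted(scores, reverse=True)
            assert [n.rank for n in nets] == list(range(1, len(nets) + 1))

    def test_no_kb_mapping_returns_empty_with_warning(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.warns(UserWarning, match="no dataset molecule"):
            assert build_networks(["x", "y"], g) == []

    def test_dataset_without_edges_gives_single_focus_networks(self):
        g = nx.empty_graph(0, create_using=nx.Graph)
        for i in range(10):
            g.add_node(f"iso{i}")
        nets = build_networks([f"iso{i}" for i in range(4)], g, n_networks=2)
        for net in nets:
            assert len(net.focus) == 1 and len(net.molecules) == 1


class TestNetworkScore:
    def test_zero_focus_scores_zero(self):
        net = Network(molecules=["a", "b"], focus=set())
        assert network_score(net, 10, 100) == pytest.approx(0.0, abs=1e-9)

    def test_exact_small_case(self):
        net = Network(molecules=[f"m{i}" for i in range(5)], focus={f"m{i}" for i in range(5)})
        p = math.comb(10, 5) / math.comb(100, 5)
        assert network_score(net, 10, 100) == pytest.approx(-math.log10(p), abs=1e-9)

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            N = int(rng.integers(10, 61))
            F = int(rng.integers(1, N))
            n = int(rng.integers(1, min(N, 36)))
            f = int(rng.integers(0, min(F, n) + 1))
            net = Network(
                molecules=[f"x{i}" for i in range(n)], focus={f"x{i}" for i in range(f)}
            )
            want = hypergeom_tail_brute(f, N, F, n)
            assert 10 ** (-network_score(net, F, N)) == pytest.approx(want, rel=1e-9)

    def test_score_increases_with_focus_count(self):
        scores = [
            network_score(
                Network(molecules=[f"x{i}" for i in range(10)], focus={f"x{i}" for i in range(f)}),
                20,
                200,
            )
            for f in range(0, 11)
        ]
        assert np.all(np.diff(scores) > 0)

    def test_invalid_sizes_rejected(self):
        net = Network(molecules=["a"], focus={"a"})
        with pytest.raises(ValueError):
            network_score(net, 200, 100)


class TestGrow:
    def _fixture(self):
        g = nx.Graph()
        core = ["A", "B", "C"]
        g.add_edges_from([("A", "B"), ("B", "C")])
        # candidates c01..c04 with 2 edges into the core, c05..c11 with 1,
        # c12 disconnected
        for c in ("c01", "c02", "c03", "c04"):
            g.add_edge(c, "A")
            g.add_edge(c, "B")
        for c in ("c05", "c06", "c07", "c08", "c09", "c10", "c11"):
            g.add_edge(c, "C")
        g.add_node("c12")
        # raise total degree of c11 so it wins the within-1-edge tie
        g.add_edge("c11", "z1")
        g.add_edge("c11", "z2")
        return g, Network(molecules=core, focus=set(core))

    def test_hand_ranked_top_n_added(self):
        g, net = self._fixture()
        grown = grow(net, [f"c{i:02d}" for i in range(1, 13)], g, n=10)
        added = [m for m in grown.molecules if m.startswith("c")]
        # 2-edge candidates first, then c11 (degree tie-break), then lexicographic
        assert added == ["c01", "c02", "c03", "c04", "c11", "c05", "c06", "c07", "c08", "c09"]

    def test_unconnected_candidate_never_added(self):
        g, net = self._fixture()
        grown = grow(net, ["c12"], g, n=10)
        assert grown.molecules == net.molecules

    def test_two_sequential_grows_add_at_most_twenty(self):
        g, net = self._fixture()
        batch1 = [f"c{i:02d}" for i in range(1, 13)]
        grown = grow(net, batch1, g, n=10)
        grown = grow(grown, batch1, g, n=10)  # re-offering adds nothing new
        assert len(grown.molecules) <= len(net.molecules) + 20


class TestMergeAndHubs:
    def _nets(self, mols_list, dataset=""):
        return [
            Network(molecules=m, focus=set(m), source_dataset=dataset, rank=i + 1)
            for i, m in enumerate(mols_list)
        ]

    def test_critical_gene_requires_both_merged_networks(self):
        nets0 = self._nets([["g1", "g2"], ["g3"]])
        nets8 = self._nets([["g1", "g4"]])
        crit = merge_and_critical_genes(nets0, nets8, {"g1", "g2", "g4"}, {"g1", "g2", "g3", "g4"})
        assert crit == {"g1"}

    def test_family_expansion_pulls_in_dataset_siblings(self):
        # g_sib absent from every network but shares a family with g1
        nets0 = self._nets([["g1"]])
        nets8 = self._nets([["g_sib"]])
        fam = {"g1": "FAM1", "g_sib": "FAM1"}
        crit = merge_and_critical_genes(
            nets0, nets8, {"g_sib"}, {"g1", "g_sib"}, family_map=fam
        )
        assert crit == {"g_sib"}

    def test_empty_network_list_rejected(self):
        with pytest.raises(ValueError):
            merge_and_critical_genes([], self._nets([["g"]]), set(), set())

    def test_hub_requires_two_distinct_datasets(self):
        g = nx.Graph()
        g.add_edges_from([("h", "a"), ("h", "b"), ("h", "c"), ("a", "b")])
        net1 = Network(molecules=["h", "a", "b"], focus={"a"}, source_dataset="d1", rank=1)
        net2 = Network(molecules=["h", "b", "c"], focus={"b"}, source_dataset="d1", rank=2)
        hubs_same = find_hubs({"d1": [net1, net2]}, g)
        assert all(h.n_datasets < 2 for h in hubs_same) or not hubs_same
        net3 = Network(molecules=["h", "a", "c"], focus={"c"}, source_dataset="d2", rank=1)
        hubs = find_hubs({"d1": [net1], "d2": [net3]}, g)
        assert "h" in {h.molecule for h in hubs}

    def test_no_hubs_without_second_dataset(self):
        g = nx.Graph()
        g.add_edge("h", "a")
        net = Network(molecules=["h", "a"], focus={"a"}, source_dataset="d1", rank=1)
        assert find_hubs({"d1": [net], "d2": []}, g) == []


class TestEnrichmentAndDirection:
    def test_perfect_overlap_is_significant(self):
        universe = {f"g{i}" for i in range(40)}
        half = {f"g{i}" for i in range(20)}
        _odds, p = gene_set_enrichment(half, half, universe)
        assert p < 1e-6

    def test_small_table_matches_enumeration(self):
        universe = {f"g{i}" for i in range(10)}
        dataset = {f"g{i}" for i in range(5)}
        gene_set = {f"g{i}" for i in range(4)} | {"g9"}
        a = len(dataset & gene_set)
        b = len(dataset - gene_set)
        c = len(gene_set - dataset)
        d = 10 - a - b - c
        _odds, p = gene_set_enrichment(dataset, gene_set, universe)
        assert p == pytest.approx(fisher_right_tail_brute(a, b, c, d), rel=1e-9)

    def test_null_enrichment_p_is_valid(self):
        # exact-test p-values on a discrete null are conservative rather
        # than uniform: check validity, P(p <= alpha) <= alpha, and that
        # small p-values are not over-produced
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        ps = []
        for _ in range(300):
            ds = set(rng.choice(universe, 40, replace=False))
            gs = set(rng.choice(universe, 30, replace=False))
            ps.append(gene_set_enrichment(ds, gs, set(universe))[1])
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.10, 0.20):
            assert np.mean(ps <= alpha) <= alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / 300)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"a"}, {"a"}, set())

    def test_direction_zscore_examples(self):
        exp = {f"g{i}": 1 for i in range(4)}
        assert direction_zscore(exp, exp) == pytest.approx(2.0)
        obs = {"g0": 1, "g1": 1, "g2": -1, "g3": -1}
        assert direction_zscore(exp, obs) == pytest.approx(0.0)
        exp9 = {f"g{i}": 1 for i in range(9)}
        obs9 = {f"g{i}": -1 for i in range(9)}
        assert direction_zscore(exp9, obs9) == pytest.approx(-3.0)
        assert direction_zscore({}, {}) is None


def test_inject_interaction_edges_adds_typed_nodes():
    g = nx.Graph()
    g.add_node("g1", type="gene", family_id="")
    out = inject_interaction_edges(g, [("miR-x", "g1"), ("miR-x", "g_new")])
    assert out.has_edge("miR-x", "g1")
    assert out.nodes["miR-x"]["type"] == "mirna"
    assert out.nodes["g_new"]["type"] == "gene"
    assert not g.has_node("miR-x")  # original untouched
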
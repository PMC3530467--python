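import networkx as nx
import numpy as np
import pytest

from netmark import search
from netmark.search import Module, SearchConfig

from conftest import random_weighted_graph, triangle_graph, wnet_from_graph


def brute_force_grow(net, seed, config):
    """Independent oracle: at every step recompute every candidate's gain
    from the definition over the raw graph and apply the stated greedy rule
    (largest positive gain, lexicographically smallest gene on ties)."""
    g = net.graph
    S = set(seed)
    while len(S) < config.max_module_size:
        candidates = sorted({v for u in S for v in g[u] if v not in S})
        best_gene, best_gain = None, 0.0
        for v in candidates:
            gain = search.modularity_gain(net, S, v, config.alpha, kind=config.gain)
            if gain > best_gain:
                best_gene, best_gain = v, gain
        if best_gene is None:
            break
        S.add(best_gene)
    return frozenset(S)


class TestEnumerateSeeds:
    def test_tree_has_no_seeds(self):
        g = nx.Graph()
        for a, b in [("A", "B"), ("B", "C"), ("C", "D")]:
            g.add_edge(a, b, weight=1.0)
        assert search.enumerate_seeds(wnet_from_graph(g)) == []

    def test_heavier_triangle_ranks_first(self):
        g = nx.Graph()
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            g.add_edge(a, b, weight=1.0)
        for a, b in [("X", "Y"), ("X", "Z"), ("Y", "Z")]:
            g.add_edge(a, b, weight=2.0)
        seeds = search.enumerate_seeds(wnet_from_graph(g))
        assert seeds == [("X", "Y", "Z"), ("A", "B", "C")]

    def test_k4_ties_break_lexicographically(self):
        g = nx.complete_graph(["A", "B", "C", "D"])
        nx.set_edge_attributes(g, 1.0, "weight")
        seeds = search.enumerate_seeds(wnet_from_graph(g))
        assert seeds == [
            ("A", "B", "C"), ("A", "B", "D"), ("A", "C", "D"), ("B", "C", "D")
        ]


class TestModularityGain:
    def test_configuration_hand_value(self):
        # single triangle, S = two nodes, v the third, alpha = 0, unit
        # weights: k_vS = 2, W_T = 6 -> gain = 1/3
        net = wnet_from_graph(triangle_graph())
        gain = search.modularity_gain(net, {"A", "B"}, "C", 0.0, kind="configuration")
        assert gain == pytest.approx(1.0 / 3.0)

    def test_configuration_strictly_decreasing_in_alpha(self):
        net = wnet_from_graph(triangle_graph())
        gains = [
            search.modularity_gain(net, {"A", "B"}, "C", a, kind="configuration")
            for a in (0.0, 0.5, 1.0, 2.0, 10.0)
        ]
        assert all(x > y for x, y in zip(gains, gains[1:]))
        assert gains[-1] < 0

    def test_configuration_scale_invariant(self):
        rng = np.random.default_rng(0)
        g = random_weighted_graph(rng, 8)
        net = wnet_from_graph(g)
        g2 = g.copy()
        for u, v, d in g2.edges(data=True):
            d["weight"] *= 2.0
        net2 = wnet_from_graph(g2)
        nodes = sorted(g.nodes)
        S = set(nodes[:3])
        for v in sorted({w for u in S for w in g[u]} - S):
            a = search.modularity_gain(net, S, v, 1.3, kind="configuration")
            b = search.modularity_gain(net2, S, v, 1.3, kind="configuration")
            assert a == pytest.approx(b)

    def test_member_and_nonadjacent_errors(self):
        net = wnet_from_graph(triangle_graph())
        with pytest.raises(ValueError, match="already"):
            search.modularity_gain(net, {"A", "B"}, "A", 1.0)
        g = triangle_graph()
        g.add_edge("X", "Y", weight=1.0)
        net = wnet_from_graph(g)
        with pytest.raises(ValueError, match="adjacent"):
            search.modularity_gain(net, {"A", "B"}, "X", 1.0)

    def test_size_normalized_matches_measure_difference(self):
        rng = np.random.default_rng(1)
        g = random_weighted_graph(rng, 8)
        net = wnet_from_graph(g)
        nodes = sorted(g.nodes)
        S = set(nodes[:3])
        for v in sorted({w for u in S for w in g[u]} - S):
            w_in = sum(d["weight"] for _, _, d in g.subgraph(S).edges(data=True))
            k_vS = sum(g[v][u]["weight"] for u in g[v] if u in S)
            expected = (w_in + k_vS) / (len(S) + 1) ** 1.4 - w_in / len(S) ** 1.4
            got = search.modularity_gain(net, S, v, 1.4, kind="size-normalized")
            assert got == pytest.approx(expected)


class TestGrowModule:
    def test_lone_triangle_is_its_own_module(self):
        net = wnet_from_graph(triangle_graph())
        mod = search.grow_module(net, ("A", "B", "C"), SearchConfig(alpha=1.0))
        assert mod.genes == {"A", "B", "C"}
        assert mod.score == pytest.approx(1.0)

    @pytest.mark.parametrize("gain", ["size-normalized", "configuration"])
    def test_two_bridged_cliques_stop_at_clique(self, gain):
        g = nx.Graph()
        a_nodes = [f"a{i}" for i in range(4)]
        b_nodes = [f"b{i}" for i in range(4)]
        for grp in (a_nodes, b_nodes):
            for i, u in enumerate(grp):
                for v in grp[i + 1:]:
                    g.add_edge(u, v, weight=1.0)
        g.add_edge("a0", "b0", weight=1.0)
        net = wnet_from_graph(g)
        cfg = SearchConfig(alpha=1.0, gain=gain)
        mod = search.grow_module(net, ("a1", "a2", "a3"), cfg)
        assert mod.genes == frozenset(a_nodes)

    @pytest.mark.parametrize("gain", ["size-normalized", "configuration"])
    def test_matches_bruteforce_oracle(self, gain):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(60):
            g = random_weighted_graph(rng, 10)
            net = wnet_from_graph(g)
            seeds = search.enumerate_seeds(net)
            if not seeds:
                continue
            cfg = SearchConfig(alpha=float(rng.uniform(0.3, 2.0)), gain=gain)
            for seed in seeds[:3]:
                expected = brute_force_grow(net, seed, cfg)
                got = search.grow_module(net, seed, cfg).genes
                assert got == expected
                checked += 1
        assert checked >= 50

    @pytest.mark.parametrize("gain", ["size-normalized", "configuration"])
    def test_alpha_to_zero_reaches_size_cap(self, gain):
        rng = np.random.default_rng(3)
        g = random_weighted_graph(rng, 9)
        if not nx.is_connected(g):
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        net = wnet_from_graph(g)
        seeds = search.enumerate_seeds(net)
        if not seeds:
            pytest.skip("triangle-free draw")
        cap = min(6, g.number_of_nodes())
        cfg = SearchConfig(alpha=1e-12, max_module_size=cap, gain=gain)
        mod = search.grow_module(net, seeds[0], cfg)
        assert len(mod.genes) == cap

    def test_scale_invariance_of_grown_set(self):
        rng = np.random.default_rng(4)
        g = random_weighted_graph(rng, 10)
        net = wnet_from_graph(g)
        seeds = search.enumerate_seeds(net)
        if not seeds:
            pytest.skip("triangle-free draw")
        g2 = g.copy()
        for _, _, d in g2.edges(data=True):
            d["weight"] *= 7.5
        net2 = wnet_from_graph(g2)
        cfg = SearchConfig(alpha=0.9)
        for seed in seeds[:3]:
            m1 = search.grow_module(net, seed, cfg)
            m2 = search.grow_module(net2, seed, cfg)
            assert m1.genes == m2.genes
            assert m2.score == pytest.approx(7.5 * m1.score)

    def test_module_contains_seed_and_is_connected(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_weighted_graph(rng, 10)
            net = wnet_from_graph(g)
            for seed in search.enumerate_seeds(net)[:2]:
                mod = search.grow_module(net, seed, SearchConfig(alpha=0.8))
                assert set(seed) <= mod.genes
                assert len(mod.genes) >= 3
                assert nx.is_connected(g.subgraph(mod.genes))


class TestScoreModule:
    def test_unit_triangle_scores_one(self):
        net = wnet_from_graph(triangle_graph())
        assert search.score_module(net, {"A", "B", "C"}) == pytest.approx(1.0)

    def test_hand_value_four_genes(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.5)
        g.add_edge("B", "C", weight=0.5)
        g.add_edge("C", "D", weight=1.0)
        net = wnet_from_graph(g)
        assert search.score_module(net, {"A", "B", "C", "D"}) == pytest.approx(0.5)

    def test_linear_in_weight_scale(self):
        rng = np.random.default_rng(6)
        g = random_weighted_graph(rng, 8)
        net = wnet_from_graph(g)
        S = sorted(g.nodes)[:4]
        g2 = g.copy()
        for _, _, d in g2.edges(data=True):
            d["weight"] *= 3.0
        net2 = wnet_from_graph(g2)
        assert search.score_module(net2, S) == pytest.approx(
            3.0 * search.score_module(net, S)
        )

    def test_small_set_errors(self):
        net = wnet_from_graph(triangle_graph())
        with pytest.raises(ValueError):
            search.score_module(net, {"A", "B"})


class TestFindModules:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for a, b in [("A", "B"), ("A", "C"), ("B", "C"),
                     ("X", "Y"), ("X", "Z"), ("Y", "Z")]:
            g.add_edge(a, b, weight=1.0)
        mods = search.find_modules(wnet_from_graph(g), SearchConfig(alpha=1.0))
        assert sorted(sorted(m.genes) for m in mods) == [list("ABC"), list("XYZ")]

    def test_k4_covered_by_first_module(self):
        g = nx.complete_graph(["A", "B", "C", "D"])
        nx.set_edge_attributes(g, 1.0, "weight")
        mods = search.find_modules(wnet_from_graph(g), SearchConfig(alpha=0.5))
        assert len(mods) == 1 and mods[0].genes == frozenset("ABCD")

    def test_gene_sets_pairwise_distinct(self):
        rng = np.random.default_rng(7)
        g = random_weighted_graph(rng, 10)
        mods = search.find_modules(wnet_from_graph(g), SearchConfig(alpha=0.8))
        sets = [m.genes for m in mods]
        assert len(sets) == len(set(sets))

    def test_redundancy_filter_drops_heavy_overlap(self):
        rng = np.random.default_rng(8)
        g = random_weighted_graph(rng, 10)
        net = wnet_from_graph(g)
        loose = search.find_modules(net, SearchConfig(alpha=0.8,
                                                      redundancy_threshold=None))
        strict = search.find_modules(net, SearchConfig(alpha=0.8,
                                                       redundancy_threshold=0.5))
        from netmark.significance import overlap_score

        assert len(strict) <= len(loose)
        for i, a in enumerate(strict):
            for b in strict[i + 1:]:
                assert overlap_score(a.genes, b.genes) <= 0.5

    def test_seed_rank_limit(self):
        g = nx.complete_graph([f"n{i}" for i in range(6)])
        nx.set_edge_attributes(g, 1.0, "weight")
        net = wnet_from_graph(g)
        all_mods = search.find_modules(net, SearchConfig(alpha=2.0))
        limited = search.find_modules(net, SearchConfig(alpha=2.0, seed_rank_limit=1))
        assert len(limited) <= len(all_mods)
        assert len(limited) == 1
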
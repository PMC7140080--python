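"""Network construction, trimming, merging, and MCODE dense regions."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scaffoldomics.networks import (build_network, mcode_dense_regions,
                                    merge_networks, select_degs, trim_network)


def edge_df(pairs, level="ppi"):
    return pd.DataFrame(pairs, columns=["source", "target"]).assign(level=level)


def clique_graph(nodes):
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(nodes, 2))
    return g


class TestSelectDegs:
    def test_strict_threshold(self):
        df = pd.DataFrame({"gene": ["a", "b"], "logFC": [1.0, -1.0],
                           "adj_p": [0.049, 0.05]})
        out = select_degs(df)
        assert out["gene"].tolist() == ["a"]

    def test_empty_table_gives_empty_list(self):
        df = pd.DataFrame({"gene": [], "logFC": [], "adj_p": []})
        assert select_degs(df).empty

    def test_all_significant_all_kept(self):
        df = pd.DataFrame({"gene": list("abc"), "logFC": [1, 2, 3],
                           "adj_p": [0.001] * 3})
        assert len(select_degs(df)) == 3


class TestBuildNetwork:
    def test_first_order_only(self):
        net = build_network({"A": 1.0}, edge_df([("A", "B"), ("B", "C")]), "ppi")
        assert set(net.nodes) == {"A", "B"}
        assert list(net.edges) == [("A", "B")]

    def test_isolated_seed_is_a_singleton_component(self):
        net = build_network({"X": 0.5}, edge_df([("A", "B")]), "ppi")
        assert set(net.nodes) == {"X"}
        assert net.graph["n_components"] == 1

    def test_empty_seed_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty seed"):
            build_network({}, edge_df([("A", "B")]), "ppi")

    def test_planted_clique_lands_in_one_component(self, network_fixture):
        _, edges, _, degt, truth = network_fixture
        degs = select_degs(degt)
        net = build_network(degs, edges[truth["clique_level"]], truth["clique_level"])
        comp = nx.node_connected_component(net, truth["clique_members"][0])
        assert set(truth["clique_members"]) <= comp

    def test_node_attributes(self):
        net = build_network({"A": 2.5}, edge_df([("A", "B")], "tf"), "tf")
        assert net.nodes["A"]["seed"] and net.nodes["A"]["logfc"] == 2.5
        assert net.nodes["B"]["type"] == "TF"


class TestTrim:
    def star(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nx.set_node_attributes(g, False, "seed")
        g.nodes["n0"]["seed"] = True
        g.graph["level"] = "ppi"
        return g

    def test_star_keeps_seed_hub_only(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = trim_network(self.star(), degree_min=2)
        assert set(out.nodes) == {"n0"}

    def test_degree_zero_keeps_everything(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = trim_network(self.star(), degree_min=0)
        assert out.number_of_nodes() == 6

    def test_budget_warning(self):
        with pytest.warns(UserWarning, match="budget"):
            trim_network(self.star(), degree_min=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_degree_threshold(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(40, 0.1, seed=int(rng.integers(1 << 30)))
        nx.set_node_attributes(g, False, "seed")
        sizes = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for dmin in range(0, 6):
                try:
                    sizes.append(trim_network(g, degree_min=dmin).number_of_nodes())
                except ValueError:
                    sizes.append(0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_all_removed_is_an_error(self):
        g = nx.path_graph(3)
        nx.set_node_attributes(g, False, "seed")
        with pytest.raises(ValueError, match="all nodes"):
            trim_network(g, degree_min=99)


class TestMerge:
    def net(self, pairs, level):
        g = nx.Graph(level=level)
        g.add_edges_from(pairs)
        nx.set_node_attributes(g, False, "seed")
        return g

    def test_simple_union_with_one_replicate_node(self):
        merged, rep = merge_networks([self.net([("A", "B")], "ppi"),
                                      self.net([("A", "C")], "tf")])
        assert merged.number_of_nodes() == 3 and merged.number_of_edges() == 2
        assert rep["n_replicate_nodes"] == 1 and rep["n_replicate_edges"] == 0
        assert rep["replicate_nodes"] == ["A"]

    def test_identical_networks_fully_replicate(self):
        n1 = self.net([("A", "B"), ("B", "C")], "ppi")
        n2 = self.net([("A", "B"), ("B", "C")], "tf")
        merged, rep = merge_networks([n1, n2])
        assert rep["n_replicate_nodes"] == 3 and rep["n_replicate_edges"] == 2
        assert merged.edges["A", "B"]["levels"] == ["ppi", "tf"]

    def test_disjoint_networks_have_no_replicates(self):
        merged, rep = merge_networks([self.net([("A", "B")], "ppi"),
                                      self.net([("C", "D")], "tf")])
        assert rep["n_replicate_nodes"] == 0 and rep["n_replicate_edges"] == 0

    def test_merge_conserves_node_union(self):
        nets = [self.net([("A", "B"), ("B", "C")], "ppi"),
                self.net([("C", "D")], "tf"),
                self.net([("E", "A")], "mirna")]
        merged, _ = merge_networks(nets)
        assert set(merged.nodes) == set().union(*(set(n.nodes) for n in nets))

    def test_fewer_than_two_is_an_error(self):
        with pytest.raises(ValueError):
            merge_networks([self.net([("A", "B")], "ppi")])


class TestMcode:
    def test_planted_clique_on_a_chain(self):
        g = clique_graph([f"c{i}" for i in range(6)])
        g.add_edges_from([("c0", "p1"), ("p1", "p2"), ("p2", "p3"), ("p3", "p4")])
        regions = mcode_dense_regions(g)
        assert regions
        assert regions[0].nodes == frozenset(f"c{i}" for i in range(6))
        # brute force: the 6-clique is the densest 6-node subgraph
        assert regions[0].score == pytest.approx(6.0)

    def test_tree_has_no_dense_regions(self):
        g = nx.balanced_tree(2, 3)
        assert mcode_dense_regions(g) == []

    def test_two_cliques_ranked_by_score(self):
        g = nx.union(clique_graph([f"a{i}" for i in range(8)]),
                     clique_graph([f"b{i}" for i in range(5)]))
        regions = mcode_dense_regions(g)
        assert len(regions) == 2
        assert regions[0].nodes == frozenset(f"a{i}" for i in range(8))
        assert regions[0].score > regions[1].score
        assert [r.rank for r in regions] == [1, 2]

    def test_regions_are_disjoint_subgraphs_with_2core(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(60, 0.08, seed=2)
        g = nx.union(nx.relabel_nodes(g, {n: f"r{n}" for n in g.nodes}),
                     clique_graph([f"k{i}" for i in range(6)]))
        regions = mcode_dense_regions(g)
        seen = set()
        for r in regions:
            assert not (r.nodes & seen)
            seen |= r.nodes
            sub = g.subgraph(r.nodes)
            assert min(dict(sub.degree()).values()) >= 2
            assert set(sub.nodes) <= set(g.nodes)

    def test_empty_graph_gives_empty_result(self):
        assert mcode_dense_regions(nx.Graph()) == []
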
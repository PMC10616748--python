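"""Interactome loading, disease-module extraction, coherence and centrality."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from premodmir import (
    PPINetwork,
    extract_lcc,
    map_gene_set,
    module_coherence,
    node_centrality,
    ppi_enrichment,
    read_interactome,
)


def net_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, score=0.9)
    g.add_nodes_from(extra_nodes)
    return PPINetwork(g)


def write_string(tmp_path, rows, name="net.tsv"):
    path = tmp_path / name
    lines = ["protein1\tprotein2\tcombined_score"]
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadInteractome:
    def test_score_threshold_is_strict(self, tmp_path):
        path = write_string(tmp_path, [("A", "B", 390), ("A", "C", 410), ("B", "C", 400)])
        net = read_interactome(path, min_score=0.4)
        assert net.graph.has_edge("A", "C")          # 0.41 kept
        assert not net.graph.has_edge("A", "B")      # 0.39 excluded
        assert not net.graph.has_edge("B", "C")      # 0.40 excluded (strict >)

    def test_symmetric_duplicates_merged_max_score(self, tmp_path):
        path = write_string(tmp_path, [("A", "B", 500), ("B", "A", 700)])
        net = read_interactome(path)
        assert net.n_edges == 1
        assert net.graph["A"]["B"]["score"] == pytest.approx(0.7)

    def test_k_valid_rows_give_k_edges(self, tmp_path):
        rows = [(f"G{i}", f"G{i+1}", 500 + i) for i in range(7)]
        net = read_interactome(write_string(tmp_path, rows))
        assert net.n_edges == 7

    def test_unit_scale_autodetected(self, tmp_path):
        path = write_string(tmp_path, [("A", "B", 0.95), ("A", "C", 0.2)])
        net = read_interactome(path)
        assert net.n_edges == 1
        assert net.graph["A"]["B"]["score"] == pytest.approx(0.95)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = write_string(tmp_path, [("A", "B", 500), ("C", "D", "oops")])
        with pytest.raises(ValueError, match="line"):
            read_interactome(path)

    def test_self_loops_dropped_and_empty_rejected(self, tmp_path):
        path = write_string(tmp_path, [("A", "A", 900)])
        with pytest.raises(ValueError, match="no edges"):
            read_interactome(path)


class TestMapGeneSet:
    def test_all_present_genes_map(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        mod = map_gene_set(net, ["a", "b", "c"])
        assert mod.mapped_genes == ["A", "B", "C"] and mod.unmapped == []

    def test_absent_symbols_reported(self):
        net = net_from_edges([("A", "B")])
        mod = map_gene_set(net, ["ZZZ9", "QQQ1", "A"])
        assert mod.mapped_genes == ["A"]
        assert set(mod.unmapped) == {"ZZZ9", "QQQ1"}

    def test_zero_mapped_raises(self):
        net = net_from_edges([("A", "B")])
        with pytest.raises(ValueError, match="map"):
            map_gene_set(net, ["X1", "X2"])

    def test_alias_table_applied(self):
        net = net_from_edges([("CXCL8", "CXCL10")])
        mod = map_gene_set(net, ["IL8"], alias={"IL8": "CXCL8"})
        assert mod.mapped_genes == ["CXCL8"]


class TestPpiEnrichment:
    def test_clique_counts_and_average_degree(self):
        clique = list(itertools.combinations("ABCDE", 2))
        net = net_from_edges(clique, extra_nodes=[f"N{i}" for i in range(40)])
        stat = ppi_enrichment(net, list("ABCDE"), n_random=200, seed=0)
        assert stat.observed_edges == 10
        assert stat.average_node_degree == pytest.approx(4.0)
        # sparse background: minimum attainable empirical p
        assert stat.empirical_p == pytest.approx(1 / 201)

    def test_random_set_p_roughly_uniform(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(120, 0.05, seed=2)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 0.9, "score")
        net = PPINetwork(g)
        nodes = np.array(list(g.nodes))
        hits = 0
        n_draws = 100
        for k in range(n_draws):
            s = rng.choice(nodes, size=12, replace=False)
            p = ppi_enrichment(net, list(s), n_random=120, seed=k).empirical_p
            hits += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_draws)
        assert hits / n_draws <= 0.05 + 3 * se + 1e-9

    def test_too_small_set_raises(self):
        net = net_from_edges([("A", "B")])
        with pytest.raises(ValueError, match="at least 2"):
            ppi_enrichment(net, ["A"], n_random=100)


class TestExtractLcc:
    def test_path_plus_pair(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("D", "E")])
        mod = extract_lcc(net, ["A", "B", "C", "D", "E"])
        assert mod.lcc_members == ["A", "B", "C"]
        assert mod.peripheral_components == [["D", "E"]]

    def test_fully_connected_has_no_periphery(self):
        net = net_from_edges(list(itertools.combinations("ABCD", 2)))
        mod = extract_lcc(net, list("ABCD"))
        assert mod.lcc_members == list("ABCD") and mod.peripheral_components == []

    def test_components_partition_mapped_set(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(60, 0.03, seed=5)
        g = nx.relabel_nodes(g, {i: f"G{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, 0.9, "score")
        net = PPINetwork(g)
        mapped = sorted(rng.choice(sorted(g.nodes), size=25, replace=False))
        mod = extract_lcc(net, mapped)
        parts = [mod.lcc_members] + mod.peripheral_components
        flat = [n for comp in parts for n in comp]
        assert sorted(flat) == sorted(mapped)  # partition incl. isolated nodes
        assert all(len(mod.lcc_members) >= len(c) for c in mod.peripheral_components)

    def test_isolated_mapped_nodes_are_singleton_components(self):
        net = net_from_edges([("A", "B")], extra_nodes=["Z"])
        mod = extract_lcc(net, ["A", "B", "Z"])
        assert mod.lcc_members == ["A", "B"]
        assert mod.peripheral_components == [["Z"]]


class TestModuleCoherence:
    def test_triangle_mean_path_is_one(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        l, n_pairs = net.mean_shortest_path(["A", "B", "C"])
        assert l == pytest.approx(1.0) and n_pairs == 3

    def test_three_path_mean_is_four_thirds(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        l, _ = net.mean_shortest_path(["A", "B", "C"])
        assert l == pytest.approx(4 / 3)

    def test_full_node_set_equals_characteristic_path_length(self):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        nx.set_edge_attributes(g, 0.9, "score")
        net = PPINetwork(g)
        l, _ = net.mean_shortest_path(sorted(g.nodes))
        assert l == pytest.approx(nx.average_shortest_path_length(g))

    def test_disconnected_pairs_excluded(self):
        net = net_from_edges([("A", "B")], extra_nodes=["Z"])
        l, n_pairs = net.mean_shortest_path(["A", "B", "Z"])
        assert l == pytest.approx(1.0) and n_pairs == 1

    def test_z_score_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(80, 0.06, seed=9)
        nx.set_edge_attributes(g, 0.9, "score")
        net1 = PPINetwork(nx.relabel_nodes(g, {i: f"A{i:02d}" for i in g.nodes}))
        # a relabeling that preserves structure and set membership
        net2 = PPINetwork(nx.relabel_nodes(g, {i: f"B{i:02d}" for i in g.nodes}))
        set1 = [f"A{i:02d}" for i in range(10)]
        set2 = [f"B{i:02d}" for i in range(10)]
        c1 = module_coherence(net1, set1, n_random=150, seed=3)
        c2 = module_coherence(net2, set2, n_random=150, seed=3)
        assert c1.z_score == pytest.approx(c2.z_score)

    def test_seed_reproducible(self):
        net, truth = __import__("premodmir").generate_ppi(n_nodes=120, module_size=15, seed=2)
        genes = sorted(truth.planted_module_genes)
        a = module_coherence(net, genes, n_random=100, seed=5)
        b = module_coherence(net, genes, n_random=100, seed=5)
        assert a.z_score == b.z_score and a.l_rand_mean == b.l_rand_mean


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: enumerate all simple paths per pair with plain
    DFS, keep the shortest, count pass-throughs; normalized by (n-1)(n-2)/2."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    adj = {v: sorted(g.neighbors(v)) for v in nodes}
    score = {v: 0.0 for v in nodes}

    def all_paths(s, t):
        stack = [(s, [s])]
        out = []
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_paths(s, t)
            if not paths:
                continue
            m = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == m]
            for p in shortest:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(shortest)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {v: s / norm for v, s in score.items()}
    return score


class TestNodeCentrality:
    def test_star_center(self):
        net = net_from_edges([("C", x) for x in "ABDE"])
        cent = node_centrality(net, list("ABCDE")).set_index("gene")
        assert cent.loc["C", "degree"] == 4
        assert cent.loc["C", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["C", "hub_rank"] == 1

    def test_path_middle_node(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        cent = node_centrality(net, ["A", "B", "C"]).set_index("gene")
        assert cent.loc["B", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["A", "betweenness"] == 0.0 and cent.loc["C", "betweenness"] == 0.0

    def test_singleton_set_zeros(self):
        net = net_from_edges([("A", "B")])
        cent = node_centrality(net, ["A"]).set_index("gene")
        assert cent.loc["A", "degree"] == 0 and cent.loc["A", "betweenness"] == 0.0

    def test_matches_brute_force_on_all_small_graphs(self):
        """Exhaustive check against path-enumeration betweenness on every
        graph with up to 7 nodes (graph atlas)."""
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for g in graph_atlas_g():
            if g.number_of_nodes() < 3 or g.number_of_edges() == 0:
                continue
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            nx.set_edge_attributes(g, 0.9, "score")
            net = PPINetwork(g)
            cent = node_centrality(net, sorted(g.nodes)).set_index("gene")
            oracle = brute_force_betweenness(g)
            for v, expected in oracle.items():
                assert cent.loc[v, "betweenness"] == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked > 900  # the atlas holds all 1253 graphs on <= 7 nodes
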
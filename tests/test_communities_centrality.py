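"""Louvain partitions, subnetwork reports and key-taxa centralities."""

import networkx as nx
import numpy as np
import pytest

from conftest import as_network
from occnet.centrality import centralities
from occnet.communities import louvain_partition, subnetwork_metrics
from occnet.topology import summarize


def two_cliques(k: int = 8):
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    g.add_edge(0, k)
    return as_network(g), k


class TestLouvain:
    def test_two_cliques_recovered_exactly(self):
        net, k = two_cliques()
        part = louvain_partition(net, seed=0)
        labels_a = {part[str(n)] for n in range(k)}
        labels_b = {part[str(n)] for n in range(k, 2 * k)}
        assert len(labels_a) == 1 and len(labels_b) == 1
        assert labels_a != labels_b

    def test_complete_graph_is_one_community(self):
        part = louvain_partition(as_network(nx.complete_graph(10)), seed=0)
        assert len(set(part.values())) == 1

    def test_partition_covers_every_node_once(self):
        net = as_network(nx.gnp_random_graph(40, 0.1, seed=1))
        part = louvain_partition(net, seed=1)
        assert set(part) == set(net.graph.nodes)

    def test_edgeless_graph_warns_and_gives_singletons(self):
        net = as_network(nx.empty_graph(5))
        with pytest.warns(UserWarning, match="edgeless"):
            part = louvain_partition(net, seed=0)
        assert len(set(part.values())) == 5

    def test_modularity_beats_trivial_partition(self):
        net, _ = two_cliques()
        part = louvain_partition(net, seed=0)
        groups = {}
        for node, lab in part.items():
            groups.setdefault(lab, set()).add(node)
        g = net.unsigned_graph()
        q_louvain = nx.community.modularity(g, groups.values())
        q_trivial = nx.community.modularity(g, [set(g.nodes)])
        assert q_louvain >= q_trivial


class TestSubnetworkMetrics:
    def test_single_group_equals_global_metrics(self):
        net = as_network(nx.gnp_random_graph(25, 0.25, seed=2))
        part = {n: 0 for n in net.graph.nodes}
        report = subnetwork_metrics(net, part)
        s = summarize(net, sw_replicates=0, seed=0)
        row = report.iloc[0]
        assert row["n_nodes"] == s.n_nodes
        assert row["n_edges"] == s.n_edges
        assert row["density"] == pytest.approx(s.density)
        assert row["clustering_coefficient"] == pytest.approx(
            s.clustering_coefficient
        )

    def test_planted_cliques_have_unit_density(self):
        net, k = two_cliques()
        part = {str(n): int(n >= k) for n in range(2 * k)}
        report = subnetwork_metrics(net, part).sort_values("group_id")
        assert list(report["density"]) == [1.0, 1.0]
        assert list(report["n_nodes"]) == [k, k]
        # the bridge edge is inter-group: intra-edge total below global
        assert report["n_edges"].sum() == net.n_edges - 1

    def test_phylum_composition_from_taxonomy(self):
        net, k = two_cliques(3)
        taxonomy = {
            "0": "Bacteria;Cyanobacteria;Cyanophyceae;Nostocales;Nostocaceae;Nostoc",
            "1": "Bacteria;Cyanobacteria;Other",
            "2": "Bacteria;Proteobacteria",
            "3": "Bacteria",
            "4": "",
        }  # node "5" missing entirely
        part = {str(n): 0 for n in range(6)}
        report = subnetwork_metrics(net, part, taxonomy=taxonomy)
        counts = report.iloc[0]["phylum_counts"]
        assert counts == {"Cyanobacteria": 2, "Proteobacteria": 1, "NA": 3}

    def test_hdbscan_noise_label_becomes_noise_group(self):
        net, k = two_cliques(3)
        part = {str(n): (-1 if n == 0 else 0) for n in range(6)}
        report = subnetwork_metrics(net, part, partition_source="hdbscan")
        noise_row = report[report["group_id"] == "noise"].iloc[0]
        assert noise_row["n_nodes"] == 1
        assert bool(noise_row["noise_like"])

    def test_group_sizes_partition_the_node_set(self):
        net = as_network(nx.gnp_random_graph(30, 0.15, seed=3))
        part = louvain_partition(net, seed=3)
        report = subnetwork_metrics(net, part)
        assert report["n_nodes"].sum() == net.n_nodes

    def test_missing_nodes_rejected(self):
        net, _ = two_cliques(3)
        with pytest.raises(ValueError, match="missing"):
            subnetwork_metrics(net, {"0": 0})


class TestCentralities:
    def test_star_center_has_maximal_degree_and_betweenness(self):
        df = centralities(as_network(nx.star_graph(5)))  # center "0" + 5 leaves
        assert df.loc["0", "degree_centrality"] == 1.0
        assert df.loc["0", "betweenness"] == 1.0
        assert df.loc["0", "rank_pagerank"] == 1

    def test_path_middle_node_closeness(self):
        df = centralities(as_network(nx.path_graph(3)))
        assert df.loc["1", "closeness"] == 1.0  # distances (1, 1)

    def test_cycle_symmetry_ties_every_metric(self):
        df = centralities(as_network(nx.cycle_graph(4)))
        for metric in ("degree_centrality", "closeness", "betweenness", "pagerank"):
            assert df[metric].nunique() == 1

    def test_pagerank_simplex_constraint(self):
        df = centralities(as_network(nx.gnp_random_graph(30, 0.1, seed=4)))
        assert df["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (df["pagerank"] > 0).all()

    def test_metrics_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(20, 0.2, seed=5)
        df1 = centralities(as_network(g))
        relabeled = nx.relabel_nodes(g, {n: f"z{n:02d}" for n in g.nodes})
        df2 = centralities(as_network(relabeled))
        for metric in ("degree_centrality", "closeness", "betweenness"):
            v1 = sorted(df1[metric])
            v2 = sorted(df2[metric])
            np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_rank_ties_break_by_taxon_id(self):
        df = centralities(as_network(nx.cycle_graph(4)))
        assert list(df.sort_values("rank_degree_centrality").index) == [
            "0", "1", "2", "3"
        ]

    def test_disconnected_closeness_uses_component_scaling(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3), (3, 4)])
        df = centralities(as_network(g))
        assert np.isfinite(df["closeness"]).all()
        # nodes in the larger component reach more of the graph
        assert df.loc["3", "closeness"] > df.loc["0", "closeness"]
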
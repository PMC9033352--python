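"""Centrality measures, hub selection, ego network, key-miRNA selection."""

import networkx as nx
import numpy as np
import pytest

from cernet import (
    CentralityRecord,
    CernetError,
    TripleNetwork,
    betweenness_centrality,
    closeness_centrality,
    compute_centralities,
    degree_centrality,
    hub_ego_network,
    select_hub_lncrna,
    select_key_mirna,
)
from cernet.datasets import load_plaque_centrality_table
from cernet.types import LNC_MI, MI_M
from tests.conftest import betweenness_by_path_counting, closeness_by_bfs


def metric_net(graph: nx.Graph) -> TripleNetwork:
    """Bypass tripartite validation: centrality is partition-agnostic."""
    net = TripleNetwork.__new__(TripleNetwork)
    relabelled = nx.Graph()
    relabelled.add_nodes_from((str(n), {"partition": "miRNA"}) for n in graph)
    relabelled.add_edges_from((str(u), str(v)) for u, v in graph.edges)
    net.graph = relabelled
    return net


class TestClosedForms:
    def test_path_graph_degrees(self):
        net = metric_net(nx.path_graph(3))
        assert degree_centrality(net) == {"0": 1, "1": 2, "2": 1}

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("a")
        net = metric_net(g)
        assert degree_centrality(net)["a"] == 0
        assert closeness_centrality(net)["a"] == 0.0

    def test_star_center(self):
        net = metric_net(nx.star_graph(4))
        assert degree_centrality(net)["0"] == 4
        assert betweenness_centrality(net)["0"] == pytest.approx(1.0)

    def test_path_closeness(self):
        clo = closeness_centrality(metric_net(nx.path_graph(3)))
        assert clo["1"] == pytest.approx(1.0)
        assert clo["0"] == pytest.approx(2 / 3)

    def test_path_betweenness_endpoints_excluded(self):
        bet = betweenness_centrality(metric_net(nx.path_graph(3)))
        assert bet["1"] == pytest.approx(1.0)
        assert bet["0"] == 0.0

    def test_per_component_normalisation_stays_in_unit_interval(self):
        g = nx.disjoint_union(nx.path_graph(5), nx.star_graph(6))
        bet = betweenness_centrality(metric_net(g))
        clo = closeness_centrality(metric_net(g))
        assert all(0 <= v <= 1 for v in bet.values())
        assert all(0 <= v <= 1 for v in clo.values())


class TestOracleAgreement:
    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(5, 31))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.5), seed=int(rng.integers(1 << 30)))
            net = metric_net(g)
            clo = closeness_centrality(net)
            bet = betweenness_centrality(net)
            clo_oracle = closeness_by_bfs(net.graph)
            bet_oracle = betweenness_by_path_counting(net.graph)
            for node in net.graph:
                assert clo[node] == pytest.approx(clo_oracle[node], abs=1e-12)
                assert bet[node] == pytest.approx(bet_oracle[node], abs=1e-12)


class TestHubSelection:
    def test_published_centrality_table_selects_hand2_as1(self):
        hub = select_hub_lncrna(load_plaque_centrality_table())
        assert hub.node == "HAND2-AS1"
        assert hub.dominant

    def test_dominant_candidate_wins(self):
        records = [
            CentralityRecord("A", "lncRNA", 10, 0.5, 0.5),
            CentralityRecord("B", "lncRNA", 8, 0.4, 0.4),
        ]
        hub = select_hub_lncrna(records)
        assert (hub.node, hub.dominant) == ("A", True)

    def test_rank_sum_fallback_flags_non_dominant(self):
        # A best in degree (rank 1+2+2=5); B best in closeness and
        # betweenness (rank 2+1+1=4) -> B wins, non-dominant
        records = [
            CentralityRecord("A", "lncRNA", 10, 0.4, 0.4),
            CentralityRecord("B", "lncRNA", 8, 0.5, 0.5),
        ]
        hub = select_hub_lncrna(records)
        assert (hub.node, hub.dominant) == ("B", False)

    def test_min_degree_filter_fatal_when_unmet(self):
        records = [CentralityRecord("A", "lncRNA", 3, 0.5, 0.5)]
        with pytest.raises(CernetError, match="degree"):
            select_hub_lncrna(records, min_degree=5)

    def test_non_lncrna_records_ignored(self):
        records = [
            CentralityRecord("G", "mRNA", 99, 0.9, 0.9),
            CentralityRecord("A", "lncRNA", 10, 0.5, 0.5),
        ]
        assert select_hub_lncrna(records).node == "A"

    def test_planted_hub_recovered(self, recovered_run):
        assert recovered_run["hub"].node == recovered_run["truth"].planted_hub


class TestEgoNetwork:
    def build(self, lnc_mi_pairs, mi_m_pairs):
        from cernet import InteractionTable, build_global

        return build_global(
            InteractionTable.from_pairs(lnc_mi_pairs, LNC_MI),
            InteractionTable.from_pairs(mi_m_pairs, MI_M),
        )

    def test_two_step_neighbourhood(self):
        net = self.build(
            [("L1", "m1"), ("L1", "m2"), ("L2", "m3")],
            [("m1", "G1"), ("m2", "G2"), ("m3", "G3")],
        )
        ego = hub_ego_network(net, "L1")
        assert set(ego.graph) == {"L1", "m1", "m2", "G1", "G2"}

    def test_hub_without_mirnas_warns(self):
        net = self.build([("L1", "m1")], [("m1", "G1")])
        net.graph.add_node("L_iso", partition="lncRNA")
        with pytest.warns(UserWarning, match="no miRNA"):
            ego = hub_ego_network(net, "L_iso")
        assert set(ego.graph) == {"L_iso"}

    def test_unknown_hub_fatal(self, tiny_network):
        with pytest.raises(CernetError):
            hub_ego_network(tiny_network, "L99")

    def test_ego_is_subgraph(self, recovered_run):
        cerna, hub = recovered_run["cerna"], recovered_run["hub"]
        ego = hub_ego_network(cerna, hub.node)
        assert ego.edge_set() <= cerna.edge_set()

    def test_planted_hub_ego_covers_all_planted_mrnas(self, recovered_run):
        cerna, truth = recovered_run["cerna"], recovered_run["truth"]
        ego = hub_ego_network(cerna, truth.planted_hub)
        hub_targets = {m for l, m in truth.planted_pairs if l == truth.planted_hub}
        assert hub_targets <= set(ego.graph)


class TestKeyMirna:
    def mirna_records(self):
        return [
            CentralityRecord("hsa-miRNA-570-3p", "miRNA", 5, 0.4164, 0.0221),
            CentralityRecord("hsa-miRNA-466", "miRNA", 5, 0.3878, 0.0145),
            CentralityRecord("hsa-miRNA-4495", "miRNA", 5, 0.3803, 0.0105),
            CentralityRecord("hsa-miRNA-999", "miRNA", 2, 0.9, 0.9),
        ]

    def hub_net(self, adjacent):
        from cernet import InteractionTable, build_global

        lnc_mi = [("HAND2-AS1", mi) for mi in adjacent]
        mi_m = [(r.node, "G1") for r in self.mirna_records()]
        return build_global(
            InteractionTable.from_pairs(lnc_mi, LNC_MI),
            InteractionTable.from_pairs(mi_m, MI_M),
        )

    def test_only_hub_adjacent_top_mirna_selected(self):
        net = self.hub_net(adjacent=["hsa-miRNA-570-3p"])
        key = select_key_mirna(self.mirna_records(), net, "HAND2-AS1", top_k=3)
        assert key == "hsa-miRNA-570-3p"

    def test_single_adjacent_mirna(self):
        net = self.hub_net(adjacent=["hsa-miRNA-4495"])
        assert select_key_mirna(self.mirna_records(), net, "HAND2-AS1") == "hsa-miRNA-4495"

    def test_no_top_k_adjacent_fatal_and_lists_candidates(self):
        net = self.hub_net(adjacent=["hsa-miRNA-999"])  # high-centrality but not top-3 by degree
        with pytest.raises(CernetError, match="hsa-miRNA-466"):
            select_key_mirna(self.mirna_records(), net, "HAND2-AS1", top_k=3)

    def test_key_mirna_adjacent_to_planted_hub(self, recovered_run):
        cerna, records, hub = (
            recovered_run["cerna"], recovered_run["records"], recovered_run["hub"],
        )
        key = select_key_mirna(records, cerna, hub.node)
        assert key in cerna.neighbors(hub.node)


def test_compute_centralities_consistent_measures(recovered_run):
    cerna, records = recovered_run["cerna"], recovered_run["records"]
    deg = degree_centrality(cerna)
    for r in records:
        assert r.degree == deg[r.node]
    assert sum(r.degree for r in records) == 2 * cerna.n_edges
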
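"""Centrality analysis and hub detection on the ceRNA network.

Three node-importance measures are computed on the undirected, unweighted
network:

* degree — the raw number of incident edges;
* closeness — (number of nodes reachable from v) / (sum of shortest-path
  distances to them), the reciprocal-of-average-distance convention used
  by Cytoscape's NetworkAnalyzer, which maps central nodes near 1;
* betweenness — exact shortest-path betweenness (endpoints excluded)
  normalised by (n−1)(n−2)/2 with n the size of the node's connected
  component, so values stay in [0, 1] even on disconnected networks.

The hub lncRNA is the node (degree ≥ 5) that is simultaneously maximal in
all three measures; when no node dominates, the best rank-sum wins and the
result is flagged as non-dominant.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .network import TripleNetwork
from .types import CentralityRecord, CernetError


def degree_centrality(network: TripleNetwork) -> dict[str, int]:
    """Raw (unnormalised) degree of every node."""
    if len(network.graph) == 0:
        raise CernetError("network is empty")
    return {node: int(deg) for node, deg in network.graph.degree()}


def closeness_centrality(network: TripleNetwork) -> dict[str, float]:
    """Reachable-count over summed-distance closeness; isolated nodes get 0."""
    if len(network.graph) == 0:
        raise CernetError("network is empty")
    # wf_improved=False gives (reachable)/(sum of distances) exactly
    return {n: float(c) for n, c in nx.closeness_centrality(network.graph, wf_improved=False).items()}


def betweenness_centrality(network: TripleNetwork) -> dict[str, float]:
    """Exact betweenness, normalised per connected component."""
    if len(network.graph) == 0:
        raise CernetError("network is empty")
    out: dict[str, float] = {}
    for component in nx.connected_components(network.graph):
        sub = network.graph.subgraph(component)
        for node, b in nx.betweenness_centrality(sub, normalized=True).items():
            out[node] = float(b)
    return out


def compute_centralities(network: TripleNetwork) -> list[CentralityRecord]:
    """All three measures for every node, sorted by descending degree."""
    deg = degree_centrality(network)
    clo = closeness_centrality(network)
    bet = betweenness_centrality(network)
    records = [
        CentralityRecord(
            node=node,
            partition=network.partition_of(node),
            degree=deg[node],
            closeness=clo[node],
            betweenness=bet[node],
        )
        for node in network.graph.nodes
    ]
    return sorted(records, key=lambda r: (-r.degree, r.node))


@dataclass(frozen=True)
class HubSelection:
    """The selected hub node and whether it dominated all three measures."""

    node: str
    dominant: bool


def select_hub_lncrna(records: list[CentralityRecord], min_degree: int = 5) -> HubSelection:
    """Pick the hub lncRNA among nodes with degree ≥ ``min_degree``.

    Returns the lncRNA maximal in degree, closeness and betweenness
    simultaneously when one exists (``dominant=True``).  Otherwise falls
    back to the smallest sum of per-measure ranks, ties broken
    lexicographically by id, flagged ``dominant=False``.
    """
    candidates = [r for r in records if r.partition == "lncRNA" and r.degree >= min_degree]
    if not candidates:
        raise CernetError(f"no lncRNA reaches the hub degree threshold {min_degree}")

    best_deg = max(r.degree for r in candidates)
    best_clo = max(r.closeness for r in candidates)
    best_bet = max(r.betweenness for r in candidates)
    for r in candidates:
        if r.degree == best_deg and r.closeness == best_clo and r.betweenness == best_bet:
            return HubSelection(node=r.node, dominant=True)

    # rank-sum fallback: rank 1 = best on each measure
    ranks = np.zeros(len(candidates))
    for values in ([-r.degree for r in candidates],
                   [-r.closeness for r in candidates],
                   [-r.betweenness for r in candidates]):
        ranks += rankdata(values, method="min")
    order = sorted(range(len(candidates)), key=lambda i: (ranks[i], candidates[i].node))
    return HubSelection(node=candidates[order[0]].node, dominant=False)


def hub_ego_network(network: TripleNetwork, hub: str) -> TripleNetwork:
    """The hub, its miRNA neighbours, their mRNA neighbours, and the
    connecting edges."""
    if hub not in network.graph:
        raise CernetError(f"hub {hub!r} not present in the network")
    mirnas = network.mirna_partners(hub)
    mrnas: set[str] = set()
    for mi in mirnas:
        mrnas |= {n for n in network.neighbors(mi) if network.partition_of(n) == "mRNA"}
    keep = {hub} | mirnas | mrnas
    if len(keep) == 1:
        import warnings

        warnings.warn(f"hub {hub!r} has no miRNA neighbours; ego network is a single node",
                      stacklevel=2)
    return TripleNetwork(nx.Graph(network.graph.subgraph(keep)))


def select_key_mirna(
    records: list[CentralityRecord],
    network: TripleNetwork,
    hub: str,
    top_k: int = 3,
) -> str:
    """Among the ``top_k`` miRNAs by centrality, return the best one
    directly adjacent to the hub.

    Ranking is by degree, ties broken by closeness, then betweenness, then
    id.  If none of the top_k touches the hub the selection fails, listing
    the candidates considered.
    """
    mirnas = [r for r in records if r.partition == "miRNA"]
    if not mirnas:
        raise CernetError("no miRNA records supplied")
    ranked = sorted(mirnas, key=lambda r: (-r.degree, -r.closeness, -r.betweenness, r.node))
    top = ranked[:top_k]
    hub_neighbors = network.neighbors(hub)
    for r in top:
        if r.node in hub_neighbors:
            return r.node
    raise CernetError(
        "none of the top-%d miRNAs (%s) directly interacts with hub %s"
        % (top_k, ", ".join(r.node for r in top), hub)
    )
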
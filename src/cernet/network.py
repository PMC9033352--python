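"""Tripartite lncRNA–miRNA–mRNA network construction.

The global triple network is the union of two bipartite interaction layers:
lncRNA–miRNA pairs and miRNA–mRNA pairs.  Edges are undirected; direction
of regulation is implied by the partition of the endpoints.  The
disease-related candidate subnetwork is obtained by mapping screened
differentially expressed lncRNAs (DELs) and mRNAs (DEMs) onto the global
network and keeping every miRNA adjacent to at least one of them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional

import networkx as nx

from .types import LNC_MI, MI_M, CernetError, DERecord, InteractionTable

logger = logging.getLogger("cernet")


class TripleNetwork:
    """An undirected tripartite graph over lncRNA, miRNA and mRNA nodes.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``partition``
    attribute (``lncRNA`` / ``miRNA`` / ``mRNA``) and whose edges carry a
    ``kind`` attribute (``lncRNA-miRNA`` / ``miRNA-mRNA``).  The tripartite
    constraint is validated at construction.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._validate()

    def _validate(self) -> None:
        kinds = {"lncRNA": LNC_MI, "mRNA": MI_M}
        for node, data in self.graph.nodes(data=True):
            if data.get("partition") not in ("lncRNA", "miRNA", "mRNA"):
                raise CernetError(f"node {node!r} lacks a valid partition label")
        for u, v, data in self.graph.edges(data=True):
            parts = {self.graph.nodes[u]["partition"], self.graph.nodes[v]["partition"]}
            kind = data.get("kind")
            if kind == LNC_MI and parts != {"lncRNA", "miRNA"}:
                raise CernetError(f"edge ({u}, {v}) labelled {kind} joins partitions {parts}")
            elif kind == MI_M and parts != {"miRNA", "mRNA"}:
                raise CernetError(f"edge ({u}, {v}) labelled {kind} joins partitions {parts}")
            elif kind not in (LNC_MI, MI_M):
                raise CernetError(f"edge ({u}, {v}) has unknown kind {kind!r}")

    # -- node / edge views --------------------------------------------------

    def _partition_nodes(self, partition: str) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d["partition"] == partition
        )

    @property
    def lnc_nodes(self) -> frozenset[str]:
        return self._partition_nodes("lncRNA")

    @property
    def mi_nodes(self) -> frozenset[str]:
        return self._partition_nodes("miRNA")

    @property
    def m_nodes(self) -> frozenset[str]:
        return self._partition_nodes("mRNA")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def partition_of(self, node: str) -> str:
        return self.graph.nodes[node]["partition"]

    def iter_edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield ``(source, target, kind)`` with the source in the upstream
        partition (lncRNA for lnc–mi edges, miRNA for mi–m edges)."""
        upstream = {LNC_MI: "lncRNA", MI_M: "miRNA"}
        for u, v, data in self.graph.edges(data=True):
            kind = data["kind"]
            if self.graph.nodes[u]["partition"] == upstream[kind]:
                yield u, v, kind
            else:
                yield v, u, kind

    def edge_set(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self.iter_edges())

    def neighbors(self, node: str) -> frozenset[str]:
        if node not in self.graph:
            raise CernetError(f"unknown node {node!r}")
        return frozenset(self.graph.neighbors(node))

    def mirna_partners(self, node: str) -> frozenset[str]:
        """miRNA neighbours of a lncRNA or mRNA node."""
        return frozenset(
            n for n in self.neighbors(node) if self.graph.nodes[n]["partition"] == "miRNA"
        )


def _graph_from_edge_lists(
    lnc_mi: Iterable[tuple[str, str]], mi_m: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Assemble the labelled graph, checking partition disjointness."""
    partition: dict[str, str] = {}

    def claim(node: str, part: str) -> None:
        prev = partition.setdefault(node, part)
        if prev != part:
            raise CernetError(
                f"identifier {node!r} appears as both {prev} and {part}: "
                "partitions must be disjoint"
            )

    graph = nx.Graph()
    for lnc, mi in lnc_mi:
        claim(lnc, "lncRNA")
        claim(mi, "miRNA")
    for mi, mrna in mi_m:
        claim(mi, "miRNA")
        claim(mrna, "mRNA")
    for node, part in partition.items():
        graph.add_node(node, partition=part)
    for lnc, mi in lnc_mi:
        graph.add_edge(lnc, mi, kind=LNC_MI)
    for mi, mrna in mi_m:
        graph.add_edge(mi, mrna, kind=MI_M)
    return graph


def build_global(lnc_mi: Optional[InteractionTable], mi_m: Optional[InteractionTable]) -> TripleNetwork:
    """Build the global triple network from the two interaction layers.

    The node set is exactly the identifiers appearing in the tables; the
    edge set the union of the deduplicated pairs.  An identifier appearing
    in two partitions (e.g. both as lncRNA and mRNA) is a fatal error.
    """
    if lnc_mi is None or mi_m is None or len(lnc_mi) == 0 or len(mi_m) == 0:
        raise CernetError("both interaction tables must be non-empty")
    if lnc_mi.edge_kind != LNC_MI:
        raise CernetError(f"first table must have edge_kind {LNC_MI!r}, got {lnc_mi.edge_kind!r}")
    if mi_m.edge_kind != MI_M:
        raise CernetError(f"second table must have edge_kind {MI_M!r}, got {mi_m.edge_kind!r}")
    return TripleNetwork(_graph_from_edge_lists(lnc_mi.pairs, mi_m.pairs))


def map_degs(
    network: TripleNetwork,
    dels: list[DERecord],
    dems: list[DERecord],
) -> TripleNetwork:
    """Induce the candidate subnetwork of screened DELs and DEMs.

    Keeps DEL lncRNAs and DEM mRNAs that are present in the global network,
    every miRNA adjacent to at least one of them, and the incident edges.
    Screened genes absent from the network are logged, not fatal; an empty
    mapping on either side is fatal (no candidate space).
    """
    lnc_present = [r.gene_id for r in dels if r.gene_id in network.lnc_nodes]
    m_present = [r.gene_id for r in dems if r.gene_id in network.m_nodes]
    missing = [r.gene_id for r in dels + dems if r.gene_id not in network.graph]
    if missing:
        logger.info("%d screened genes absent from the global network: %s",
                    len(missing), ", ".join(sorted(missing)[:10]))
    if not lnc_present:
        raise CernetError("no differentially expressed lncRNA maps into the network")
    if not m_present:
        raise CernetError("no differentially expressed mRNA maps into the network")

    keep = set(lnc_present) | set(m_present)
    mirnas = set()
    for node in keep:
        mirnas |= network.mirna_partners(node)
    sub = nx.Graph()
    for node in keep | mirnas:
        sub.add_node(node, partition=network.partition_of(node))
    for u, v, data in network.graph.edges(data=True):
        if u in sub and v in sub and (u in keep or v in keep):
            sub.add_edge(u, v, kind=data["kind"])
    return TripleNetwork(sub)


def shared_mirnas(network: TripleNetwork, lnc: str, mrna: str) -> frozenset[str]:
    """miRNAs adjacent to both a lncRNA and an mRNA (candidate sponge set)."""
    if lnc not in network.lnc_nodes:
        raise CernetError(f"{lnc!r} is not a lncRNA node of this network")
    if mrna not in network.m_nodes:
        raise CernetError(f"{mrna!r} is not an mRNA node of this network")
    return network.neighbors(lnc) & network.neighbors(mrna)
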
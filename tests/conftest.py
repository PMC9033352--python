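"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pytest

from cernet import SyntheticConfig, TripleNetwork, build_global, InteractionTable
from cernet.types import LNC_MI, MI_M


# ---------------------------------------------------------------------------
# independent oracles (never call the code paths they check)

def hypergeom_tail_by_enumeration(K: int, M: int, N: int) -> dict[int, float]:
    """Exact overlap distribution by enumerating every N-subset of a
    K-universe whose first M elements are 'marked'.  Returns, for each
    possible X, the strictly-greater tail P(T > X)."""
    marked = set(range(M))
    counts: dict[int, int] = {}
    total = 0
    for draw in combinations(range(K), N):
        total += 1
        x = len(marked.intersection(draw))
        counts[x] = counts.get(x, 0) + 1
    tails = {}
    for x in range(min(M, N) + 1):
        above = sum(c for t, c in counts.items() if t > x)
        tails[x] = above / total
    return tails


def closeness_by_bfs(graph: nx.Graph) -> dict:
    """Reachable-count over summed-distance closeness via plain BFS."""
    out = {}
    for node in graph:
        dist = nx.single_source_shortest_path_length(graph, node)
        del dist[node]
        out[node] = len(dist) / sum(dist.values()) if dist else 0.0
    return out


def betweenness_by_path_counting(graph: nx.Graph) -> dict:
    """Betweenness via all-pairs shortest-path counting (not Brandes).

    For each ordered source, count shortest paths sigma[s][v] by BFS layer
    DP; a node v lies on sigma_sv * sigma_vt / sigma_st of the s-t shortest
    paths when d(s,v) + d(v,t) = d(s,t).  Normalised by (n-1)(n-2)/2 per
    connected component, endpoints excluded.
    """
    nodes = list(graph)
    dist = {s: nx.single_source_shortest_path_length(graph, s) for s in nodes}
    sigma = {}
    for s in nodes:
        counts = {s: 1}
        for v in sorted(dist[s], key=dist[s].get):
            if v == s:
                continue
            counts[v] = sum(
                counts[u] for u in graph.neighbors(v)
                if u in dist[s] and dist[s][u] == dist[s][v] - 1
            )
        sigma[s] = counts
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    score[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    out = {}
    for comp in nx.connected_components(graph):
        n = len(comp)
        denom = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
        for v in comp:
            out[v] = score[v] / denom
    return out


def bh_by_stepup(pvalues: list[float]) -> list[float]:
    """Hand-rolled BH step-up: q_i = min_{j>=i} p_(j) * m / j, input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def tiny_network() -> TripleNetwork:
    """L1-{m1,m2}-G1, L2-{m2,m3}-G2 with full mi-m wiring for m2."""
    lnc_mi = InteractionTable.from_pairs(
        [("L1", "m1"), ("L1", "m2"), ("L2", "m2"), ("L2", "m3")], LNC_MI
    )
    mi_m = InteractionTable.from_pairs(
        [("m1", "G1"), ("m2", "G1"), ("m2", "G2"), ("m3", "G2")], MI_M
    )
    return build_global(lnc_mi, mi_m)


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def recovered_run():
    """One full synthetic pipeline run shared across tests."""
    from cernet import (
        assemble_cerna_network,
        compute_centralities,
        compute_de,
        generate_expression,
        generate_interactions,
        map_degs,
        screen,
        select_hub_lncrna,
        test_all_pairs,
    )

    config = SyntheticConfig(seed=11)
    lnc_mi, mi_m, truth = generate_interactions(config)
    matrix = generate_expression(config, truth)
    screened = screen(compute_de(matrix), "methods")
    global_net = build_global(lnc_mi, mi_m)
    dels = [r for r in screened if r.gene_id in lnc_mi.sources]
    dems = [r for r in screened if r.gene_id in mi_m.targets]
    candidate = map_degs(global_net, dels, dems)
    pairs = test_all_pairs(candidate, global_network=global_net)
    cerna = assemble_cerna_network(pairs)
    records = compute_centralities(cerna)
    hub = select_hub_lncrna(records)
    return {
        "config": config, "truth": truth, "global": global_net,
        "candidate": candidate, "pairs": pairs, "cerna": cerna,
        "records": records, "hub": hub, "dels": dels, "dems": dems,
    }
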
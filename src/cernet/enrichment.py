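"""Over-representation analysis with kappa-statistic term grouping.

A query gene list is tested against each set of a GMT collection with the
inclusive hypergeometric upper tail P(T ≥ overlap) over a finite gene
universe (by default the union of all collection members).  Terms passing
the raw significance filter (P < 0.05 by default — no FDR at this stage)
are then clustered into functional groups: two terms are linked when the
Cohen's kappa agreement of their membership vectors on the universe
reaches a threshold (0.4 by default, the ClueGO convention), and connected
components of that term graph become groups, numbered by their best
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx

from .cerna import hypergeom_excess_tail
from .types import CernetError, GeneSetCollection


@dataclass(frozen=True)
class EnrichmentRecord:
    """ORA result for one term of the collection."""

    term_id: str
    term_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    pvalue: float
    group_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValueError("overlap cannot exceed min(set size, query size)")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue outside [0, 1]")


def ora_test(query: set[str], term_set: set[str], universe: set[str]) -> float:
    """Inclusive hypergeometric upper-tail p-value of the query/term overlap."""
    if not universe:
        raise CernetError("universe must be non-empty")
    if not query <= universe:
        raise CernetError("query genes must be a subset of the universe")
    if not term_set <= universe:
        raise CernetError("term genes must be a subset of the universe")
    overlap = len(query & term_set)
    return hypergeom_excess_tail(
        len(universe), len(term_set), len(query), overlap, tail="inclusive"
    )


def kappa_score(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa between two membership indicator vectors on the universe.

    Returns 1.0 by convention when chance agreement is perfect (both sets
    empty or both equal to the whole universe).
    """
    if len(universe) < 2:
        raise CernetError("universe must contain at least 2 genes")
    if not set_a <= universe or not set_b <= universe:
        raise CernetError("sets must be subsets of the universe")
    n = len(universe)
    a = len(set_a & set_b)                  # in both
    b = len(set_a - set_b)                  # A only
    c = len(set_b - set_a)                  # B only
    d = n - a - b - c                       # in neither
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: Optional[set[str]] = None,
    p_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test the query against every term; return records with P < threshold.

    The universe defaults to the union of all collection members; query
    genes outside it are dropped (they carry no information about the
    annotated space).  Results are sorted by ascending p-value.
    """
    if universe is None:
        universe = collection.all_members
    query_in = query & universe
    records = []
    for term_id, (name, members) in collection.sets.items():
        p = ora_test(query_in, set(members), universe)
        if p < p_threshold:
            records.append(
                EnrichmentRecord(
                    term_id=term_id,
                    term_name=name,
                    overlap=len(query_in & members),
                    set_size=len(members),
                    query_size=len(query_in),
                    universe_size=len(universe),
                    pvalue=p,
                )
            )
    return sorted(records, key=lambda r: (r.pvalue, r.term_id))


def group_terms(
    records: list[EnrichmentRecord],
    sets: GeneSetCollection,
    universe: set[str],
    kappa_threshold: float = 0.4,
) -> list[EnrichmentRecord]:
    """Assign group ids to enriched terms by kappa-similarity clustering.

    Terms whose gene memberships agree with kappa ≥ threshold are linked;
    connected components become groups, numbered from 1 in order of each
    group's best (smallest) p-value.
    """
    if not records:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(r.term_id for r in records)
    ids = [r.term_id for r in records]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if kappa_score(set(sets.members(a)), set(sets.members(b)), universe) >= kappa_threshold:
                graph.add_edge(a, b)

    best_p = {r.term_id: r.pvalue for r in records}
    components = sorted(
        nx.connected_components(graph),
        key=lambda comp: (min(best_p[t] for t in comp), min(comp)),
    )
    group_of = {}
    for gid, comp in enumerate(components, start=1):
        for term in comp:
            group_of[term] = gid
    return [replace(r, group_id=group_of[r.term_id]) for r in records]
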
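"""Competing-RNA pair detection by the hypergeometric shared-miRNA test.

For a candidate lncRNA–mRNA pair, let K be the number of miRNAs in the
universe, M the number related to the mRNA, N the number related to the
lncRNA and X the number they share.  Under the null of independent miRNA
sets, the shared count T follows a hypergeometric distribution, and the
pair's p-value is the excess tail

    P = 1 − Σ_{t=0..X} C(M, t) · C(K−M, N−t) / C(K, N) = P(T > X),

i.e. the probability of sharing *more* miRNAs than observed.  This strict
form deliberately excludes the observed overlap from the tail; the
conventional inclusive tail P(T ≥ X) is available via ``tail="inclusive"``.
P-values over all candidate pairs are Benjamini–Hochberg adjusted and pairs
with FDR below the threshold (default 0.01) form the ceRNA network.

The tail probability is accumulated in log-space (log-gamma binomials +
log-sum-exp), so it remains accurate when K is in the hundreds of
thousands, as in genome-wide interaction databases.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .network import TripleNetwork, _graph_from_edge_lists
from .types import CernetError, CeRNAPair

TAILS = ("literal", "inclusive")


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def hypergeom_excess_tail(K: int, M: int, N: int, X: int, *, tail: str = "literal") -> float:
    """Tail probability of the shared-miRNA hypergeometric null.

    ``tail="literal"`` returns P(T > X) (the observed overlap excluded from
    the tail); ``tail="inclusive"`` returns the conventional P(T ≥ X).
    The result is clamped to [0, 1].
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if not (0 <= M <= K and 0 <= N <= K):
        raise CernetError(f"require 0 <= M, N <= K; got K={K}, M={M}, N={N}")
    if not 0 <= X <= min(M, N):
        raise CernetError(f"require 0 <= X <= min(M, N); got X={X}, M={M}, N={N}")

    lo = X + 1 if tail == "literal" else X
    hi = min(M, N)
    support_min = max(0, N - (K - M))
    if lo <= support_min:
        return 1.0  # tail covers the whole support exactly
    if lo > hi:
        return 0.0
    t = np.arange(lo, hi + 1)
    log_terms = _log_binom(M, t) + _log_binom(K - M, N - t) - _log_binom(K, N)
    return float(min(1.0, max(0.0, np.exp(logsumexp(log_terms)))))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.isnan(arr).any():
        raise CernetError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(arr, method="fdr_bh")[1]]


def test_all_pairs(
    subnetwork: TripleNetwork,
    global_network: Optional[TripleNetwork] = None,
    universe_size: int | str = "auto",
    tail: str = "literal",
) -> list[CeRNAPair]:
    """Test every candidate lncRNA–mRNA pair of a subnetwork.

    Candidates are all (lncRNA, mRNA) pairs of the subnetwork that share at
    least one miRNA; pairs sharing none cannot act as competing RNAs and
    are excluded rather than diluting the FDR.  The per-node miRNA counts
    M and N (and the shared set) are taken from ``global_network`` — the
    full interaction universe — not from the induced subnetwork;
    ``universe_size="auto"`` uses the global network's total miRNA count K.
    """
    ref = global_network if global_network is not None else subnetwork
    if universe_size == "auto":
        K = len(ref.mi_nodes)
    else:
        K = int(universe_size)

    pairs: list[CeRNAPair] = []
    raw: list[float] = []
    for lnc in sorted(subnetwork.lnc_nodes):
        n_lnc = ref.mirna_partners(lnc)
        if len(n_lnc) > K:
            raise CernetError(f"universe K={K} smaller than N={len(n_lnc)} for {lnc}")
        for mrna in sorted(subnetwork.m_nodes):
            n_m = ref.mirna_partners(mrna)
            if len(n_m) > K:
                raise CernetError(f"universe K={K} smaller than M={len(n_m)} for {mrna}")
            shared = n_lnc & n_m
            if not shared:
                continue
            p = hypergeom_excess_tail(K, len(n_m), len(n_lnc), len(shared), tail=tail)
            pairs.append(
                CeRNAPair(
                    lnc=lnc, mrna=mrna, K=K, M=len(n_m), N=len(n_lnc),
                    X=len(shared), shared=frozenset(shared), pvalue=p,
                )
            )
            raw.append(p)
    for pair, fdr in zip(pairs, bh_adjust(raw)):
        pair.fdr = fdr
    return pairs


test_all_pairs.__test__ = False  # name starts with "test"; not a pytest case


class CeRNANetwork(TripleNetwork):
    """The significant competing-RNA network plus its pair annotations."""

    def __init__(self, graph, pairs: list[CeRNAPair]):
        super().__init__(graph)
        self.pairs = pairs


def assemble_cerna_network(pairs: list[CeRNAPair], fdr_threshold: float = 0.01) -> CeRNANetwork:
    """Assemble the network of pairs significant at ``fdr < fdr_threshold``.

    Nodes are the significant pairs' lncRNAs, mRNAs and shared miRNAs;
    edges connect each lncRNA and mRNA to the miRNAs they competitively
    share.  If no pair is significant an empty network is returned with a
    warning rather than an error.
    """
    significant = [p for p in pairs if p.fdr < fdr_threshold]
    if not significant:
        warnings.warn(
            f"no competing pair significant at FDR < {fdr_threshold}; network is empty",
            stacklevel=2,
        )
        import networkx as nx

        return CeRNANetwork(nx.Graph(), [])

    lnc_mi, mi_m = set(), set()
    for pair in significant:
        for mi in pair.shared:
            lnc_mi.add((pair.lnc, mi))
            mi_m.add((mi, pair.mrna))
    graph = _graph_from_edge_lists(sorted(lnc_mi), sorted(mi_m))
    return CeRNANetwork(graph, significant)
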
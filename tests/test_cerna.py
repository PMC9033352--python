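"""Hypergeometric shared-miRNA test, BH adjustment, ceRNA network assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from cernet import (
    CernetError,
    CeRNAPair,
    assemble_cerna_network,
    bh_adjust,
    hypergeom_excess_tail,
    test_all_pairs,
)
from tests.conftest import bh_by_stepup, hypergeom_tail_by_enumeration


class TestExcessTail:
    def test_overlap_at_maximum_has_zero_tail(self):
        assert hypergeom_excess_tail(5, 5, 3, 3) == 0.0

    @pytest.mark.parametrize(
        "K,M,N,X,expected",
        [
            (4, 2, 2, 0, 5 / 6),       # enumeration: 5 of C(4,2)=6 draws overlap > 0
            (6, 3, 2, 1, 0.2),          # 3 of C(6,2)=15 draws overlap 2
            (20, 8, 6, 3, 7 / 51),      # frozen from exhaustive C(20,6) enumeration
        ],
    )
    def test_enumerated_values(self, K, M, N, X, expected):
        assert hypergeom_excess_tail(K, M, N, X) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_small_grid(self):
        """Spot-check the log-space computation against full enumeration."""
        for K in (5, 8):
            for M in range(K + 1):
                for N in range(K + 1):
                    tails = hypergeom_tail_by_enumeration(K, M, N)
                    for X, expected in tails.items():
                        got = hypergeom_excess_tail(K, M, N, X)
                        assert got == pytest.approx(expected, abs=1e-12), (K, M, N, X)

    def test_cross_check_against_scipy_survival(self):
        for K, M, N, X in [(300, 40, 25, 7), (1000, 120, 90, 20), (50, 10, 10, 2)]:
            assert hypergeom_excess_tail(K, M, N, X) == pytest.approx(
                float(hypergeom.sf(X, K, M, N)), rel=1e-10
            )

    def test_inclusive_tail_adds_observed_term(self):
        literal = hypergeom_excess_tail(20, 8, 6, 3, tail="literal")
        inclusive = hypergeom_excess_tail(20, 8, 6, 3, tail="inclusive")
        pmf = float(hypergeom.pmf(3, 20, 8, 6))
        assert inclusive == pytest.approx(literal + pmf, abs=1e-12)

    def test_large_universe_remains_finite_and_sane(self):
        p = hypergeom_excess_tail(500_000, 3000, 2000, 50)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(float(hypergeom.sf(50, 500_000, 3000, 2000)), rel=1e-8)

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_monotone_nonincreasing_in_overlap(self, data):
        K = data.draw(st.integers(2, 40))
        M = data.draw(st.integers(0, K))
        N = data.draw(st.integers(0, K))
        tails = [hypergeom_excess_tail(K, M, N, X) for X in range(min(M, N) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
        assert tails[-1] == 0.0  # maximal overlap cannot be exceeded

    def test_invalid_arguments_fatal(self):
        with pytest.raises(CernetError):
            hypergeom_excess_tail(5, 6, 2, 1)
        with pytest.raises(CernetError):
            hypergeom_excess_tail(5, 3, 2, 3)


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.04]) == [pytest.approx(0.04)]

    def test_stepup_collapses_equal_spacing(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_out_of_range_fatal(self):
        with pytest.raises(CernetError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_hand_stepup_and_dominates_input(self, pvalues):
        adjusted = bh_adjust(pvalues)
        assert adjusted == pytest.approx(bh_by_stepup(pvalues), abs=1e-12)
        assert all(q >= p - 1e-12 for p, q in zip(pvalues, adjusted))
        assert all(0 <= q <= 1 for q in adjusted)


class TestTestAllPairs:
    def test_all_pairs_with_sharing_are_tested(self, tiny_network):
        # L1 and L2 both share a miRNA with both G1 and G2 via m2 / m1 / m3
        pairs = test_all_pairs(tiny_network)
        tested = {(p.lnc, p.mrna) for p in pairs}
        assert tested == {("L1", "G1"), ("L1", "G2"), ("L2", "G1"), ("L2", "G2")}

    def test_disjoint_pair_excluded(self):
        from cernet import InteractionTable, build_global
        from cernet.types import LNC_MI, MI_M

        net = build_global(
            InteractionTable.from_pairs([("L1", "m1"), ("L2", "m2")], LNC_MI),
            InteractionTable.from_pairs([("m1", "G1"), ("m2", "G2")], MI_M),
        )
        tested = {(p.lnc, p.mrna) for p in test_all_pairs(net)}
        assert tested == {("L1", "G1"), ("L2", "G2")}

    def test_counts_taken_from_global_network(self, tiny_network):
        from cernet import DERecord, map_degs

        sub = map_degs(
            tiny_network,
            dels=[DERecord("L1", 2.0, 1e-3)],
            dems=[DERecord("G1", 2.0, 1e-3)],
        )
        (pair,) = [p for p in test_all_pairs(sub, global_network=tiny_network)]
        # in the global network L1 has 2 miRNAs, G1 has 2, universe has 3
        assert (pair.K, pair.M, pair.N) == (3, 2, 2)

    def test_planted_pair_has_smallest_pvalue(self, recovered_run):
        pairs = recovered_run["pairs"]
        planted = set(map(tuple, recovered_run["truth"].planted_pairs))
        best = min(pairs, key=lambda p: p.pvalue)
        assert (best.lnc, best.mrna) in planted

    def test_universe_smaller_than_neighbourhood_fatal(self, tiny_network):
        with pytest.raises(CernetError, match="universe"):
            test_all_pairs(tiny_network, universe_size=1)

    def test_fdr_dominates_pvalue(self, recovered_run):
        for pair in recovered_run["pairs"]:
            assert pair.fdr >= pair.pvalue - 1e-12


class TestAssemble:
    def make_pair(self, lnc, mrna, shared, fdr):
        return CeRNAPair(
            lnc=lnc, mrna=mrna, K=100, M=10, N=10, X=len(shared),
            shared=frozenset(shared), pvalue=fdr / 2, fdr=fdr,
        )

    def test_single_pair_network_shape(self):
        net = assemble_cerna_network([self.make_pair("L1", "G1", {"m1", "m2"}, 0.005)])
        assert len(net.graph) == 4
        assert net.n_edges == 4

    def test_no_significant_pair_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no competing pair"):
            net = assemble_cerna_network([self.make_pair("L1", "G1", {"m1"}, 0.5)])
        assert len(net.graph) == 0

    def test_threshold_is_strict(self):
        with pytest.warns(UserWarning):
            net = assemble_cerna_network(
                [self.make_pair("L1", "G1", {"m1"}, 0.01)], fdr_threshold=0.01
            )
        assert len(net.graph) == 0

    def test_planted_recovery_no_decoys(self, recovered_run):
        cerna, truth = recovered_run["cerna"], recovered_run["truth"]
        significant = {(p.lnc, p.mrna) for p in cerna.pairs}
        assert significant == set(map(tuple, truth.planted_pairs))

    def test_every_lnc_and_mrna_in_a_significant_pair(self, recovered_run):
        cerna = recovered_run["cerna"]
        in_pairs = {p.lnc for p in cerna.pairs} | {p.mrna for p in cerna.pairs}
        assert cerna.lnc_nodes | cerna.m_nodes == in_pairs

    def test_tripartite_invariants_hold(self, recovered_run):
        cerna = recovered_run["cerna"]
        degrees = dict(cerna.graph.degree())
        assert sum(degrees.values()) == 2 * cerna.n_edges
        for u, v, kind in cerna.iter_edges():
            assert kind in ("lncRNA-miRNA", "miRNA-mRNA")


class TestNullCalibration:
    def test_inclusive_tail_is_conservative_under_random_wiring(self):
        """With no planted sharing, the conventional inclusive-tail
        p-value P(T >= X) falls below 0.05 in at most ~5% of candidate
        pairs (3 binomial SEs of slack); every lncRNA x mRNA pair counts.
        The exclusive tail P(T > X) omits the observed overlap's own
        probability mass and is therefore anti-conservative on discrete
        data; only the inclusive form can satisfy this calibration."""
        from cernet import SyntheticConfig, build_global, generate_interactions

        config = SyntheticConfig(
            seed=101, n_planted_lnc=0, n_planted_mrna=0, background_edge_prob=0.05
        )
        lnc_mi, mi_m, _ = generate_interactions(config)
        net = build_global(lnc_mi, mi_m)
        K = len(net.mi_nodes)
        pvalues = []
        for lnc in net.lnc_nodes:
            n_lnc = net.mirna_partners(lnc)
            for mrna in net.m_nodes:
                n_m = net.mirna_partners(mrna)
                pvalues.append(
                    hypergeom_excess_tail(
                        K, len(n_m), len(n_lnc), len(n_lnc & n_m), tail="inclusive"
                    )
                )
        frac = np.mean([p < 0.05 for p in pvalues])
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(pvalues))
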
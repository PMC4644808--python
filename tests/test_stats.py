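import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, mannwhitneyu

from listwise.core import Background, InteractionNetwork
from listwise.stats import (
    ContingencyTable,
    CorrectionInput,
    contingency,
    correct_bh_fdr,
    correct_bonferroni,
    correct_holm,
    fisher_twotailed,
    interaction_sum,
    permutation_interaction_test,
    wilcoxon_ranksum,
)

from oracles import (
    bh_stepup_flags,
    fisher_twotailed_exact,
    holm_adjusted,
    ranksum_exact_twosided_dp,
    wilcoxon_twosided_enumeration,
)


class TestContingency:
    def test_hand_enumerated_five_gene_example(self):
        tbl = contingency(
            {"g1", "g2"}, {"g2", "g3"}, {"g1", "g2", "g3", "g4", "g5"}
        )
        assert (tbl.n11, tbl.n12, tbl.n21, tbl.n22) == (1, 1, 1, 2)

    def test_query_equals_universe(self):
        tbl = contingency({"g1", "g2"}, {"g1"}, {"g1", "g2"})
        assert tbl.n12 == 0 and tbl.n22 == 0

    def test_set_outside_background_vanishes(self):
        tbl = contingency({"g1"}, {"x", "y"}, {"g1", "g2"})
        assert tbl.n11 == 0 and tbl.n12 == 0

    def test_cells_sum_to_background(self):
        tbl = contingency({"g1", "g3"}, {"g2", "g3"}, {f"g{i}" for i in range(10)})
        assert tbl.n_total == 10

    def test_empty_background_error(self):
        with pytest.raises(ValueError, match="background"):
            contingency({"g1"}, {"g1"}, set())

    def test_query_outside_background_error(self):
        with pytest.raises(ValueError):
            contingency({"gX"}, {"g1"}, {"g1"})


class TestFisherTwoTailed:
    def test_symmetric_table_matches_rational_enumeration(self):
        p = fisher_twotailed(ContingencyTable(3, 1, 1, 3)).raw_p
        expected = float(fisher_twotailed_exact(3, 1, 1, 3))
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.4857142857, rel=1e-9)

    def test_zero_overlap_with_zero_expectation_is_one(self):
        res = fisher_twotailed(ContingencyTable(0, 0, 3, 4))
        assert res.raw_p == 1.0
        assert "degenerate margins" in res.warnings

    def test_direction_over_and_under(self):
        assert fisher_twotailed(ContingencyTable(5, 1, 1, 5)).direction == "over"
        assert fisher_twotailed(ContingencyTable(0, 6, 6, 0)).direction == "under"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            cells = rng.integers(0, 30, size=4)
            tbl = ContingencyTable(*map(int, cells))
            if min(tbl.n_query, tbl.n_set) == 0 or min(
                tbl.n12 + tbl.n22, tbl.n21 + tbl.n22
            ) < 0:
                continue
            ours = fisher_twotailed(tbl).raw_p
            ref = fisher_exact(
                [[tbl.n11, tbl.n12], [tbl.n21, tbl.n22]], alternative="two-sided"
            )[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_exhaustive_small_universes_match_rational_oracle(self):
        """All tables with |B| <= 8 agree exactly with same-margin
        enumeration in rational arithmetic (full sweep at 12 lives in the
        acceptance suite)."""
        for n in range(1, 9):
            for n11 in range(n + 1):
                for n12 in range(n - n11 + 1):
                    for n21 in range(n - n11 - n12 + 1):
                        n22 = n - n11 - n12 - n21
                        tbl = ContingencyTable(n11, n12, n21, n22)
                        res = fisher_twotailed(tbl)
                        expected = float(
                            fisher_twotailed_exact(n11, n12, n21, n22)
                        )
                        if res.warnings:  # degenerate margins report p = 1
                            assert res.raw_p == 1.0
                        else:
                            assert res.raw_p == pytest.approx(
                                expected, rel=1e-10
                            )


class TestWilcoxonRankSum:
    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert res.raw_p == 1.0
        assert res.method == "wilcoxon_exact"

    def test_fully_separated_triples(self):
        res = wilcoxon_ranksum([10, 11, 12], [1, 2, 3])
        assert res.raw_p == pytest.approx(2 / math.comb(6, 3))
        assert res.direction == "over"

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        # integers force ties to exercise midranks
        x = list(rng.integers(0, 6, size=n).astype(float))
        y = list(rng.integers(0, 6, size=m).astype(float))
        res = wilcoxon_ranksum(x, y)
        assert res.method == "wilcoxon_exact"
        assert res.raw_p == pytest.approx(wilcoxon_twosided_enumeration(x, y))

    def test_normal_path_close_to_exact_for_moderate_sizes(self):
        rng = np.random.default_rng(7)
        x = list(rng.normal(0.3, 1, size=20))
        y = list(rng.normal(0, 1, size=20))
        res = wilcoxon_ranksum(x, y)
        assert res.method == "wilcoxon_normal"
        w = int(round(res.statistic))
        assert res.raw_p == pytest.approx(
            ranksum_exact_twosided_dp(20, 20, w), abs=0.01
        )

    def test_normal_path_close_to_scipy_tie_free(self):
        rng = np.random.default_rng(11)
        x = list(rng.normal(0.5, 1, size=25))
        y = list(rng.normal(0, 1, size=40))
        res = wilcoxon_ranksum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1]
        assert res.raw_p == pytest.approx(ref, abs=1e-6)

    def test_warnings_small_list_many_combinations_high_p(self):
        rng = np.random.default_rng(2)
        x = list(rng.normal(size=5))
        y = list(rng.normal(size=30))
        res = wilcoxon_ranksum(x, y)
        joined = " ".join(res.warnings)
        assert "below 10" in joined
        assert "2500" in joined

    def test_high_p_warning(self):
        res = wilcoxon_ranksum([1.0, 4.0], [2.0, 3.0])
        assert any("0.25" in w for w in res.warnings)

    def test_empty_side_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestInteractionSum:
    NET = InteractionNetwork.from_pairs(
        [("g1", "g2"), ("g2", "g4")], kind="physical"
    )

    def test_internal_edge_counted_once(self):
        assert interaction_sum({"g1", "g2", "g3"}, self.NET) == 1

    def test_disjoint_query_zero(self):
        assert interaction_sum({"x", "y"}, self.NET) == 0

    def test_complete_graph_on_four(self):
        genes = ["a", "b", "c", "d"]
        net = InteractionNetwork.from_pairs(
            list(itertools.combinations(genes, 2)), kind="physical"
        )
        assert interaction_sum(set(genes), net) == 6


class TestPermutationTest:
    def _toy(self):
        clique = [f"q{i}" for i in range(5)]
        pool = [f"b{i:03d}" for i in range(100)]
        edges = list(itertools.combinations(clique, 2)) + [
            (pool[2 * i], pool[2 * i + 1]) for i in range(20)
        ]
        net = InteractionNetwork.from_pairs(edges, kind="physical")
        return clique, net, Background(frozenset(clique + pool))

    def test_best_case_p_is_two_per_thousand(self):
        clique, net, bg = self._toy()
        res = permutation_interaction_test(clique, net, bg, n_perm=1000, seed=5)
        assert res.raw_p == 0.002
        assert res.details["exceed_count"] <= 1

    def test_unenriched_query_p_capped_at_one(self):
        _, net, bg = self._toy()
        lonely = [f"q{i}" for i in range(5)]  # no internal edges
        # densely connected pool: most random draws contain an edge
        net2 = InteractionNetwork.from_pairs(
            [
                (f"b{i:03d}", f"b{j:03d}")
                for i in range(40)
                for j in range(i + 1, 40)
            ],
            kind="physical",
        )
        res = permutation_interaction_test(lonely, net2, bg, n_perm=1000, seed=0)
        assert res.raw_p == 1.0

    def test_pool_guard_returns_no_p(self):
        net = InteractionNetwork.from_pairs([("a", "b")], kind="physical")
        bg = Background(frozenset(["a", "b", "c", "d", "e"]))
        res = permutation_interaction_test({"a", "b", "c"}, net, bg, seed=0)
        assert res.raw_p is None
        assert any("too large" in w for w in res.warnings)

    def test_invariant_under_gene_relabeling(self):
        clique, net, bg = self._toy()
        mapping = {g: f"X_{g}" for g in bg.genes}
        net2 = InteractionNetwork.from_pairs(
            [(mapping[a], mapping[b]) for a, b in net.edges], kind="physical"
        )
        bg2 = Background(frozenset(mapping.values()))
        r1 = permutation_interaction_test(clique, net, bg, n_perm=2000, seed=9)
        r2 = permutation_interaction_test(
            [mapping[g] for g in clique], net2, bg2, n_perm=2000, seed=9
        )
        assert r1.raw_p == r2.raw_p

    def test_seed_determinism(self):
        clique, net, bg = self._toy()
        r1 = permutation_interaction_test(clique, net, bg, n_perm=500, seed=3)
        r2 = permutation_interaction_test(clique, net, bg, n_perm=500, seed=3)
        assert r1.raw_p == r2.raw_p
        assert r1.details == r2.details


class TestCorrections:
    def test_bonferroni_direct_product_and_cap(self):
        assert correct_bonferroni(CorrectionInput([0.001] * 100)) == pytest.approx(
            [0.1] * 100
        )
        assert correct_bonferroni(CorrectionInput([0.5] * 10)) == [1.0] * 10
        assert correct_bonferroni(CorrectionInput([0.37])) == [pytest.approx(0.37)]

    def test_holm_stepdown_hand_example(self):
        assert correct_holm(CorrectionInput([0.01, 0.02])) == pytest.approx(
            [0.02, 0.02]
        )

    def test_holm_single_p_equals_bonferroni(self):
        inp = CorrectionInput([0.03])
        assert correct_holm(inp) == correct_bonferroni(inp)

    def test_holm_all_equal_stay_equal(self):
        adj = correct_holm(CorrectionInput([0.02] * 5))
        assert len(set(np.round(adj, 12))) == 1

    def test_bh_hand_example_first_two_significant(self):
        adj, flags = correct_bh_fdr(
            CorrectionInput([0.001, 0.004, 0.04, 0.5], alpha=0.01)
        )
        assert flags == [True, True, False, False]

    def test_bh_all_ones(self):
        adj, flags = correct_bh_fdr(CorrectionInput([1.0] * 6))
        assert adj == [1.0] * 6 and not any(flags)

    def test_t_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CorrectionInput([0.1, 0.2], t=5)

    @pytest.mark.parametrize("seed", range(8))
    def test_algebra_against_independent_implementations(self, seed):
        rng = np.random.default_rng(seed)
        ps = list(rng.random(size=int(rng.integers(1, 60))))
        alpha = float(rng.choice([0.01, 0.05, 0.1]))
        inp = CorrectionInput(ps, alpha=alpha)
        bonf = correct_bonferroni(inp)
        holm = correct_holm(inp)
        bh, flags = correct_bh_fdr(inp)
        # element-wise ordering and caps
        for p, h, b, q in zip(ps, holm, bonf, bh):
            assert p <= h + 1e-12 <= b + 1e-12
            assert q <= b + 1e-12
            assert 0 <= min(h, b, q) and max(h, b, q) <= 1
        assert holm == pytest.approx(holm_adjusted(ps))
        assert flags == bh_stepup_flags(ps, alpha)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=40,
    )
)
def test_correction_ordering_property(ps):
    """For any p vector: bonferroni >= holm >= raw element-wise, BH <=
    bonferroni, everything capped at 1."""
    inp = CorrectionInput(ps)
    bonf = correct_bonferroni(inp)
    holm = correct_holm(inp)
    bh, _ = correct_bh_fdr(inp)
    for p, h, b, q in zip(ps, holm, bonf, bh):
        assert p <= h + 1e-12 <= b + 1e-12
        assert q <= b + 1e-12
        assert max(h, b, q) <= 1.0


def test_fisher_null_calibration_is_conservative():
    """Random queries vs random binary features: the raw Fisher p <= alpha
    fraction stays at or below alpha (+3 Monte-Carlo sigma); discreteness
    makes the test conservative."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(200)]
    bg = Background(frozenset(genes))
    alpha = 0.05
    n_tests = 0
    n_hits = 0
    for _ in range(30):
        A = set(rng.choice(genes, size=25, replace=False))
        for _ in range(60):
            G = set(rng.choice(genes, size=int(rng.integers(5, 40)), replace=False))
            p = fisher_twotailed(contingency(A, G, bg)).raw_p
            n_tests += 1
            n_hits += p <= alpha
    rate = n_hits / n_tests
    assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_tests)
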
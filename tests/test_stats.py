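"""Overlap, rank, FDR and clustering primitives against exact oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from exoantigen.errors import DataError
from exoantigen.stats import (
    annotation_set_enrichment,
    bh_fdr,
    correlation_cluster,
    fisher_exact,
    hypergeometric_overlap,
    mann_whitney,
    t_test_unpaired,
)

from _oracles import (
    auc_by_pair_counting,
    bh_step_up,
    fisher_two_sided,
    hypergeom_by_enumeration,
    hypergeom_upper_tail,
)


class TestHypergeometricOverlap:
    def test_toy_example_matches_enumeration(self):
        res = hypergeometric_overlap(3, 4, 5, 10)
        assert res.p_upper == pytest.approx(float(Fraction(66, 252)), abs=1e-12)
        assert res.p_upper == pytest.approx(
            float(hypergeom_by_enumeration(3, 4, 5, 10)), abs=1e-12
        )

    def test_zero_overlap_has_p_one(self):
        assert hypergeometric_overlap(0, 4, 5, 10).p_upper == 1.0

    def test_exact_agreement_on_small_universes(self):
        for N in range(2, 13):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(K, n) + 1):
                        expected = float(hypergeom_upper_tail(k, K, n, N))
                        got = hypergeometric_overlap(k, K, n, N).p_upper
                        assert abs(got - expected) < 1e-12, (k, K, n, N)

    def test_representation_factor_formula(self):
        res = hypergeometric_overlap(19, 92, 1097, 17611)
        assert res.representation_factor == 19 * 17611 / (92 * 1097)

    @pytest.mark.parametrize("bad", [(5, 4, 5, 10), (1, 11, 5, 10), (1, 4, 11, 10)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(DataError):
            hypergeometric_overlap(*bad)


class TestFisherExact:
    def test_hand_enumerated_two_sided(self):
        _, p = fisher_exact([[3, 1], [1, 3]])
        assert p == pytest.approx(float(Fraction(34, 70)), abs=1e-12)
        assert p == pytest.approx(float(fisher_two_sided([[3, 1], [1, 3]])), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_perfect_diagonal_is_minimal_p(self, n):
        _, p = fisher_exact([[0, n], [n, 0]])
        assert p == pytest.approx(2 / comb(2 * n, n), abs=1e-12)

    def test_identical_rows_give_p_one(self):
        _, p = fisher_exact([[4, 6], [4, 6]])
        assert p == pytest.approx(1.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[0, 0], [0, 0]])


class TestMannWhitney:
    def test_pair_counting_oracle(self):
        res = mann_whitney([2.0, 4.0], [1.0, 3.0])
        assert res.u_statistic == 3.0
        assert res.auc == pytest.approx(
            float(auc_by_pair_counting([2, 4], [1, 3]))
        )
        assert res.auc == 0.75

    def test_perfect_separation(self):
        res = mann_whitney([0.9, 0.8, 0.7], [0.6, 0.5])
        assert res.auc == 1.0
        assert res.method == "exact"

    def test_identical_groups(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.auc == 0.5
        assert res.p_value == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=7)
        a = mann_whitney(x, y)
        b = mann_whitney(y, x)
        assert a.auc == pytest.approx(1.0 - b.auc, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_exact_method_used_for_small_tie_free_samples(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / comb(4, 2))

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestTTest:
    def test_equal_groups_degenerate_convention(self):
        assert t_test_unpaired([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_one_sided_is_half_of_two_sided_for_pooled_variance(self):
        x, y = [3.0, 4.0, 5.0], [1.0, 2.0, 3.0]
        two = t_test_unpaired(x, y, "two-sided", equal_var=True)
        one = t_test_unpaired(x, y, "greater", equal_var=True)
        assert one == pytest.approx(two / 2)

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            t_test_unpaired(rng.normal(size=10), rng.normal(size=10)) < 0.05
            for _ in range(400)
        )
        # binomial 99% band around 400 * 0.05 = 20
        assert 8 <= rejections <= 33


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_step_up_recursion(self, rng):
        p = rng.uniform(size=25)
        np.testing.assert_allclose(bh_fdr(p), bh_step_up(list(p)), atol=1e-12)

    def test_single_p_unchanged_and_output_dominates_input(self, rng):
        assert bh_fdr([0.2])[0] == 0.2
        p = rng.uniform(size=12)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.2])


class TestCorrelationCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["a", "b", "c"],
        )
        dend = correlation_cluster(m)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(dend.linkage[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_rows_at_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        dend = correlation_cluster(m)
        assert dend.heights[-1] == pytest.approx(2.0)

    def test_column_permutation_leaves_heights_unchanged(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 10)))
        perm = rng.permutation(10)
        a = correlation_cluster(m)
        b = correlation_cluster(m.iloc[:, perm])
        np.testing.assert_allclose(a.heights, b.heights, atol=1e-12)

    def test_heights_non_decreasing(self, rng):
        m = pd.DataFrame(rng.normal(size=(8, 12)))
        heights = correlation_cluster(m).heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_constant_row_named_in_error(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(DataError, match="flat"):
            correlation_cluster(m)


class TestAnnotationSetEnrichment:
    def test_exact_term_ranks_first_and_disjoint_is_one(self):
        query = {"g1", "g2", "g3"}
        sets = {"match": {"g1", "g2", "g3"}, "other": {"g8", "g9"}}
        out = annotation_set_enrichment(query, sets, universe=10)
        assert out.iloc[0]["term"] == "match"
        disjoint = out.set_index("term").loc["other"]
        assert disjoint["p"] == 1.0

    def test_toy_universe_matches_enumeration(self):
        query = {"g1", "g2", "g3", "g4", "g5"}
        sets = {"t1": {"g1", "g2", "g3", "g6"}, "t2": {"g4", "g9"}}
        out = annotation_set_enrichment(query, sets, universe=10).set_index("term")
        assert out.loc["t1", "p"] == pytest.approx(
            float(hypergeom_by_enumeration(3, 4, 5, 10)), abs=1e-12
        )
        assert out.loc["t2", "p"] == pytest.approx(
            float(hypergeom_by_enumeration(1, 2, 5, 10)), abs=1e-12
        )

    def test_empty_query_rejected(self):
        with pytest.raises(DataError):
            annotation_set_enrichment([], {"t": {"g"}}, universe=10)
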
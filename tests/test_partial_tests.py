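"""Partial test statistics and their permutation distributions."""

from itertools import combinations
from math import comb, log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from npcperm.errors import ConfigurationError, DegenerateVariableError
from npcperm.partial_tests import lr_statistic, mean_diff_statistic, partial_test
from npcperm.permutation_engine import PermutationScheme

from conftest import build_cohort

EXACT = PermutationScheme(exact_threshold=10**6)


def brute_force_partial_p(x1, x2, stat):
    """Independent full-enumeration oracle: recompute ``stat`` over every
    split of the pooled values and count splits at least as extreme."""
    pooled = list(x1) + list(x2)
    n1 = len(x1)
    t_obs = stat(pooled[:n1], pooled[n1:])
    count = total = 0
    for picks in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in picks]
        b = [pooled[i] for i in range(len(pooled)) if i not in picks]
        if stat(a, b) >= t_obs - 1e-12 * max(1.0, abs(t_obs)):
            count += 1
        total += 1
    return count / total


def crosstab_stat(levels):
    def stat(a, b):
        counts = [[a.count(l) for l in levels], [b.count(l) for l in levels]]
        return lr_statistic(counts)

    return stat


class TestMeanDiffStatistic:
    def test_identical_groups_give_zero(self):
        assert mean_diff_statistic([3, 7], [3, 7]) == 0.0

    def test_hand_value(self):
        assert mean_diff_statistic([1, 3], [2, 6]) == pytest.approx(2.0)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
        st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, x1, x2, c):
        base = mean_diff_statistic(x1, x2)
        scaled = mean_diff_statistic([c * v for v in x1], [c * v for v in x2])
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)

    def test_studentized_variant_is_scale_invariant(self):
        x1, x2 = [1.0, 3.0, 2.0], [5.0, 9.0, 4.0]
        a = mean_diff_statistic(x1, x2, studentize=True)
        b = mean_diff_statistic([10 * v for v in x1], [10 * v for v in x2], studentize=True)
        assert a == pytest.approx(b)


class TestLrStatistic:
    def test_identical_row_proportions_give_zero(self):
        assert lr_statistic([[5, 5], [10, 10]]) == pytest.approx(0.0)

    def test_perfect_separation_hand_value(self):
        assert lr_statistic([[10, 0], [0, 10]]) == pytest.approx(40 * log(2))

    def test_zero_column_contributes_nothing(self):
        assert lr_statistic([[3, 2, 0], [1, 4, 0]]) == pytest.approx(
            lr_statistic([[3, 2], [1, 4]])
        )

    def test_zero_row_rejected(self):
        with pytest.raises(DegenerateVariableError):
            lr_statistic([[0, 0], [3, 7]])

    def test_malformed_table_rejected(self):
        with pytest.raises(ConfigurationError):
            lr_statistic([[1, 2, 3]])

    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=4),
        st.lists(st.integers(0, 30), min_size=2, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_independent_g_test(self, r1, r2):
        """Cross-check against scipy's log-likelihood-ratio contingency test."""
        l = min(len(r1), len(r2))
        table = np.array([r1[:l], r2[:l]], dtype=float)
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            return
        g, _, _, _ = chi2_contingency(table, correction=False, lambda_="log-likelihood")
        assert lr_statistic(table) == pytest.approx(float(g), rel=1e-10, abs=1e-10)


class TestPartialTest:
    def test_exact_separated_numeric_example(self, tiny_numeric_cohort):
        res = partial_test(tiny_numeric_cohort, "x", EXACT)
        assert res.exact
        assert res.t_obs == pytest.approx(9.0)
        # the identity split and its complement both attain |Δmean| = 9, and
        # the absolute statistic is complement-symmetric: 2 of 6 splits
        assert res.raw_p == pytest.approx(2 / 6)

    def test_identical_group_multisets_give_p_one(self, numeric_spec):
        t = build_cohort([1, 1, 2, 2], {"x": [4.0, 8.0, 8.0, 4.0]}, [numeric_spec])
        res = partial_test(t, "x", EXACT)
        assert res.raw_p == 1.0

    def test_first_permuted_statistic_is_observed(self, tiny_numeric_cohort):
        res = partial_test(tiny_numeric_cohort, "x", EXACT)
        assert res.t_perm[0] == res.t_obs

    def test_label_swap_leaves_result_unchanged(self, numeric_spec, binary_spec):
        cols = {
            "x": [1.0, 5.0, 2.0, 9.0, 3.0, 7.0],
            "status": ["yes", "no", "yes", "no", "no", "no"],
        }
        g = [1, 1, 1, 2, 2, 2]
        swapped = [3 - c for c in g]
        for var in ("x", "status"):
            a = partial_test(build_cohort(g, cols, [numeric_spec, binary_spec]), var, EXACT)
            b = partial_test(
                build_cohort(swapped, cols, [numeric_spec, binary_spec]), var, EXACT
            )
            assert a.t_obs == pytest.approx(b.t_obs)
            assert a.raw_p == pytest.approx(b.raw_p)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_numeric_matches_brute_force(self, seed, numeric_spec):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5, size=2)
        x = rng.normal(size=n1 + n2)
        t = build_cohort([1] * n1 + [2] * n2, {"x": x.tolist()}, [numeric_spec])
        res = partial_test(t, "x", EXACT)
        expected = brute_force_partial_p(
            x[:n1], x[n1:], lambda a, b: abs(np.mean(a) - np.mean(b))
        )
        assert res.raw_p == expected  # bit-for-bit

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_categorical_matches_brute_force(self, seed, binary_spec):
        rng = np.random.default_rng(100 + seed)
        n1, n2 = rng.integers(2, 5, size=2)
        vals = rng.choice(["yes", "no"], size=n1 + n2).tolist()
        if len(set(vals)) < 2:
            vals[0] = "yes" if vals[1] == "no" else "no"
        t = build_cohort([1] * n1 + [2] * n2, {"status": vals}, [binary_spec])
        res = partial_test(t, "status", EXACT)
        expected = brute_force_partial_p(
            vals[:n1], vals[n1:], crosstab_stat(("yes", "no"))
        )
        assert res.raw_p == expected

    def test_cmc_estimate_consistent_with_exact(self, numeric_spec):
        """CMC raw p lies within 3 binomial SEs of the exact value."""
        rng = np.random.default_rng(77)
        x = rng.normal(size=9).tolist()
        t = build_cohort([1] * 4 + [2] * 5, {"x": x}, [numeric_spec])
        p_exact = partial_test(t, "x", EXACT).raw_p
        failures = 0
        for seed in range(20):
            cmc = PermutationScheme(n_permutations=2000, seed=seed, exact_threshold=0)
            p_cmc = partial_test(t, "x", cmc).raw_p
            if abs(p_cmc - p_exact) > 3 * np.sqrt(p_exact * (1 - p_exact) / 2000):
                failures += 1
        assert failures <= 1

    def test_degenerate_single_level_flags_not_crashes(self, binary_spec):
        t = build_cohort(
            [1, 1, 2, 2], {"status": ["yes", "yes", "yes", "yes"]}, [binary_spec]
        )
        with pytest.warns(UserWarning, match="single observed level"):
            res = partial_test(t, "status", EXACT)
        assert res.degenerate and res.raw_p == 1.0

    def test_missing_units_removed_for_this_variable_only(self, numeric_spec):
        t = build_cohort(
            [1, 1, 1, 2, 2, 2], {"x": [1.0, None, 2.0, 8.0, 9.0, 10.0]}, [numeric_spec]
        )
        res = partial_test(t, "x", EXACT)
        assert (res.n1, res.n2) == (2, 3)
        assert res.n_assignments == comb(5, 2)

    def test_shared_assignments_restrict_to_complete_cases(self, numeric_spec):
        """With a shared unit-level assignment matrix, the restricted identity
        row must reproduce the observed labeling of the complete cases."""
        t = build_cohort(
            [1, 1, 1, 2, 2, 2], {"x": [1.0, None, 2.0, 8.0, 9.0, 10.0]}, [numeric_spec]
        )
        rng = np.random.default_rng(5)
        assignments = np.zeros((50, 6), dtype=bool)
        assignments[0] = t.groups == 1
        for r in range(1, 50):
            assignments[r] = rng.permutation(assignments[0])
        res = partial_test(t, "x", EXACT, assignments=assignments)
        assert res.t_perm[0] == res.t_obs
        assert res.t_obs == pytest.approx(abs(np.mean([1.0, 2.0]) - np.mean([8, 9, 10])))
        assert res.n_assignments == 50
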
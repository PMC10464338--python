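"""Comparison statistics checked against enumeration and resampling oracles."""

import itertools
import math

import numpy as np
import pytest

from hexelute import (
    ValidationError,
    bh_fdr,
    chi_square_independence,
    hypergeometric_enrichment,
    mann_whitney_u,
    quartile_split,
    t_test_independent,
)


def chi2_oracle(table):
    """Pearson statistic from the explicit expected-count formula."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return ((table - expected) ** 2 / expected).sum()


def mann_whitney_exact_oracle(x, y):
    """U for x and the exact two-sided p by enumerating rank arrangements."""
    pooled = sorted(x + y)
    ranks_x = [pooled.index(v) + 1 for v in x]
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks_x) - n1 * (n1 + 1) / 2
    all_ranks = range(1, n1 + n2 + 1)
    u_values = [
        sum(combo) - n1 * (n1 + 1) / 2
        for combo in itertools.combinations(all_ranks, n1)
    ]
    total = len(u_values)
    p_low = sum(u <= u_obs for u in u_values) / total
    p_high = sum(u >= u_obs for u in u_values) / total
    return u_obs, min(1.0, 2 * min(p_low, p_high))


def hypergeom_pmf_oracle(k, M, n, N):
    """P(X = k) for overlap k, universe M, set n, query N, by direct counting."""
    return math.comb(n, k) * math.comb(M - n, N - k) / math.comb(M, N)


class TestChiSquare:
    def test_symmetric_two_by_two(self):
        chi2, df, p = chi_square_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3)  # all expected counts are 15
        assert df == 1
        assert 0 < p < 1

    def test_identical_rows_give_zero_statistic(self):
        chi2, df, p = chi_square_independence([[5, 7, 9], [5, 7, 9]])
        assert chi2 == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_doubling_counts_doubles_statistic(self):
        table = [[12, 5, 8], [3, 9, 14]]
        chi2_a, _, _ = chi_square_independence(table)
        chi2_b, _, _ = chi_square_independence([[2 * v for v in row] for row in table])
        assert chi2_b == pytest.approx(2 * chi2_a)

    def test_matches_explicit_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(1, 50, size=(2, rng.integers(2, 6)))
            chi2, df, p = chi_square_independence(table)
            assert chi2 == pytest.approx(chi2_oracle(table))
            assert df == table.shape[1] - 1

    def test_zero_marginal_errors(self):
        with pytest.raises(ValidationError):
            chi_square_independence([[0, 0], [5, 5]])


class TestTTest:
    def test_identical_samples_give_t_zero_p_one(self):
        t, _, p = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swapping_samples_negates_t(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t_xy, _, p_xy = t_test_independent(x, y)
        t_yx, _, p_yx = t_test_independent(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_constant_equal_samples_convention(self):
        t, _, p = t_test_independent([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_other_zero_variance_errors(self):
        with pytest.raises(ValidationError):
            t_test_independent([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValidationError):
            t_test_independent([2.0, 2.0], [1.0, 5.0])

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 1.0, size=20)
        y = rng.normal(0.6, 1.0, size=20)
        t_obs, _, p = t_test_independent(x, y)
        pooled = np.concatenate([x, y])
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            px, py = perm[: len(x)], perm[len(x) :]
            t_perm, _, _ = t_test_independent(px, py)
            count += abs(t_perm) >= abs(t_obs)
        p_perm = count / n_perm
        se = math.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) <= 3 * se + 1 / n_perm


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6, 3)

    def test_identical_samples_give_half_of_product(self):
        u, _ = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)

    def test_u_conservation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=8)
        u_x, _ = mann_whitney_u(x, y)
        u_y, _ = mann_whitney_u(y, x)
        assert u_x + u_y == pytest.approx(len(x) * len(y))

    def test_matches_enumeration_oracle_on_small_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # no ties
            x, y = list(pooled[:n1]), list(pooled[n1:])
            u, p = mann_whitney_u(x, y)
            u_exp, p_exp = mann_whitney_exact_oracle(x, y)
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp)

    def test_large_or_tied_samples_use_normal_approximation(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0, 6.0]
        _, p = mann_whitney_u(x, y)  # ties force the approximation
        assert 0 < p <= 1


class TestHypergeometricEnrichment:
    def test_full_overlap_probability(self):
        universe = {f"U{i}" for i in range(20)}
        query = {f"U{i}" for i in range(5)}
        results = hypergeometric_enrichment(query, {"setA": set(query)}, universe)
        assert results[0].overlap == 5
        assert results[0].p_value == pytest.approx(1 / math.comb(20, 5))

    def test_set_outside_universe_is_skipped(self):
        universe = {"A", "B", "C", "D"}
        results = hypergeometric_enrichment(
            {"A"}, {"inside": {"A", "B"}, "outside": {"Z"}}, universe
        )
        assert [r.set_name for r in results] == ["inside"]

    def test_matches_pmf_summation_oracle_for_all_overlaps(self):
        universe = [f"U{i}" for i in range(10)]
        set_members = set(universe[:4])
        for overlap in range(4):
            query = universe[:overlap] + universe[4 : 4 + (3 - overlap)]
            results = hypergeometric_enrichment(
                set(query), {"s": set_members}, universe
            )
            expected = sum(hypergeom_pmf_oracle(k, 10, 4, 3) for k in range(overlap, 4))
            assert results[0].overlap == overlap
            assert results[0].p_value == pytest.approx(expected)

    def test_overwhelming_overlap_keeps_p_positive(self):
        universe = {f"U{i}" for i in range(2000)}
        members = {f"U{i}" for i in range(500)}
        results = hypergeometric_enrichment(members, {"s": members}, universe)
        assert 0 < results[0].p_value <= 1
        assert 0 < results[0].q_value <= 1

    def test_query_must_be_inside_universe(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"Z"}, {"s": {"A"}}, {"A", "B"})

    def test_empty_query_or_universe_errors(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(set(), {"s": {"A"}}, {"A"})
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"A"}, {"s": {"A"}}, set())


class TestBhFdr:
    def test_step_up_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_preserves_p_value_ranking(self):
        rng = np.random.default_rng(11)
        p = list(rng.uniform(size=25))
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestQuartileSplit:
    def test_eight_values_two_per_bin(self):
        values = {f"P{i}": float(i) for i in range(1, 9)}
        bins = quartile_split(values)
        counts = {b: list(bins.values()).count(b) for b in ("Q1", "Q2", "Q3", "Q4")}
        assert counts == {"Q1": 2, "Q2": 2, "Q3": 2, "Q4": 2}
        assert bins["P8"] == "Q4" and bins["P1"] == "Q1"

    def test_all_equal_values_split_deterministically(self):
        values = {f"P{i}": 1.0 for i in range(8)}
        bins = quartile_split(values)
        assert list(bins.values()).count("Q1") == 2
        assert bins["P0"] == "Q1" and bins["P7"] == "Q4"  # lexicographic ties

    def test_insertion_order_irrelevant(self):
        values = {f"P{i}": float(i % 3) for i in range(12)}
        shuffled = dict(reversed(list(values.items())))
        assert quartile_split(values) == quartile_split(shuffled)

    def test_too_few_values_error(self):
        with pytest.raises(ValidationError):
            quartile_split({f"P{i}": float(i) for i in range(7)})
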
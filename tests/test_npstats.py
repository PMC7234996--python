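import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pikw.npstats import (
    EmpiricalNull,
    GroupedSample,
    empirical_p,
    empirical_percentile,
    kruskal_wallis,
    kw_h,
    kw_h_matrix,
    mann_whitney,
    midranks,
)


class TestMidranks:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 20, 20, 30], [1, 2.5, 2.5, 4]),
            ([5], [1]),
            ([7, 7, 7], [2, 2, 2]),
        ],
    )
    def test_textbook_examples(self, values, expected):
        np.testing.assert_array_equal(midranks(values), expected)

    def test_ranks_sum_to_triangular_number(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 5, size=30).astype(float)  # plenty of ties
        assert midranks(v).sum() == 30 * 31 / 2

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            midranks([1.0, np.nan])


class TestKruskalWallis:
    def test_no_tie_hand_value(self):
        res = kruskal_wallis(GroupedSample([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1]))
        assert res.H == pytest.approx(3.857142857)
        assert res.chisq_p == pytest.approx(0.0495, abs=5e-4)

    def test_tie_correction_hand_value(self):
        # uncorrected H = 2.4, C = 1 - (2*(8-2))/(64-4) = 0.8, H = 3.0
        res = kruskal_wallis(GroupedSample([1, 1, 2, 2], [0, 0, 1, 1]))
        assert res.H == pytest.approx(3.0)

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis(GroupedSample([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]))
        assert res.H == pytest.approx(0.0)

    def test_all_values_tied_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            h = kw_h(np.array([4.0, 4.0, 4.0, 4.0]), np.array([0, 0, 1, 1]))
        assert h == 0.0

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 8, size=rng.integers(3, 9)).astype(float)
                      for _ in range(k)]
            values = np.concatenate(groups)
            labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
            if np.unique(values).size == 1:
                continue
            ours = kruskal_wallis(GroupedSample(values, labels))
            ref = stats.kruskal(*groups)
            assert ours.H == pytest.approx(ref.statistic)
            assert ours.chisq_p == pytest.approx(ref.pvalue)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        # integer-valued floats: the transforms below stay injective (no
        # underflow/overflow collisions that would alter the rank structure)
        values=st.lists(st.integers(-30, 30), min_size=6, max_size=14, unique=True),
        split=st.integers(2, 4),
    )
    def test_invariant_under_monotone_transform(self, values, split):
        values = np.asarray(values, dtype=float)
        labels = np.arange(len(values)) % split
        h0 = kw_h(values, labels)
        for f in (lambda x: 3 * x + 2, np.exp, lambda x: x**3):
            assert kw_h(f(values), labels) == pytest.approx(h0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kw_h(np.array([1.0, 2.0]), np.array([0, 0]))


def _enumeration_p(a, b):
    """Brute-force exact two-sided MW p over all C(n, n1) rank assignments."""
    n1, n2 = len(a), len(b)
    pooled = sorted(a + b)
    u_obs = sum(1 for x in a for y in b if x > y)
    center = n1 * n2 / 2
    count = total = 0
    for subset in itertools.combinations(range(n1 + n2), n1):
        chosen = [pooled[i] for i in subset]
        rest = [pooled[i] for i in range(n1 + n2) if i not in subset]
        u = sum(1 for x in chosen for y in rest if x > y)
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            count += 1
    return count / total


class TestMannWhitney:
    def test_exact_hand_value(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.p_two_sided == pytest.approx(0.100)
        assert res.method == "exact"

    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.U == pytest.approx(4.5)
        assert res.p_two_sided == 1.0

    def test_large_separated_significant(self):
        res = mann_whitney(list(range(1, 11)), list(range(11, 21)))
        assert res.method == "normal-approximation"
        assert res.p_two_sided < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (2, 6), (4, 4), (4, 6), (5, 5)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        values = list(range(1, n1 + n2 + 1))
        for subset in itertools.combinations(values, n1):
            a = list(subset)
            b = [v for v in values if v not in subset]
            ours = mann_whitney(a, b)
            assert ours.method == "exact"
            assert ours.p_two_sided == pytest.approx(_enumeration_p(a, b))

    def test_h_u_closed_form_all_small_partitions(self):
        # for tie-free k=2 data: H = 12 (U - n1 n2 / 2)^2 / (n1 n2 (N+1))
        for n1, n2 in [(2, 3), (3, 3), (3, 5), (4, 4)]:
            n = n1 + n2
            values = list(range(1, n + 1))
            for subset in itertools.combinations(values, n1):
                a = np.array(subset, dtype=float)
                b = np.array([v for v in values if v not in subset], dtype=float)
                labels = np.array([0] * n1 + [1] * n2)
                h = kw_h(np.concatenate([a, b]), labels)
                u = mann_whitney(a, b).U
                expected = 12 * (u - n1 * n2 / 2) ** 2 / (n1 * n2 * (n + 1))
                assert h == pytest.approx(expected, abs=1e-9)


class TestEmpiricalNull:
    def test_percentile_nearest_rank(self):
        assert empirical_percentile(np.arange(1.0, 1001.0), 95) == 950.0
        assert empirical_percentile(np.arange(1.0, 21.0), 95) == 19.0
        assert empirical_percentile(np.full(100, 2.5), 95) == 2.5

    def test_percentile_domain(self):
        with pytest.raises(ValueError):
            empirical_percentile(np.arange(100.0), 0)
        with pytest.raises(ValueError):
            empirical_percentile(np.arange(100.0), 100)

    def test_empirical_p_boundaries(self):
        below = np.arange(999.0)  # all below observed 1000
        assert empirical_p(below, 1000.0)[0] == pytest.approx(0.001)
        assert empirical_p(np.array([5.0, 6.0, 7.0]), 6.0) == (0.75, 2 / 3)
        above = np.arange(1.0, 1000.0)
        assert empirical_p(above, 0.0)[0] == 1.0

    def test_container_validates(self):
        with pytest.raises(ValueError):
            EmpiricalNull(np.array([1.0, -2.0]), 2, 0, "x")
        with pytest.raises(ValueError):
            EmpiricalNull(np.array([1.0]), 2, 0, "x")


def test_kw_h_matrix_agrees_with_scalar():
    rng = np.random.default_rng(4)
    values = rng.normal(size=(12, 20))
    values[:, 3] = np.round(values[:, 3])  # force a tied column
    labels = np.array([0] * 5 + [1] * 7)
    h = kw_h_matrix(values, labels)
    for c in range(values.shape[1]):
        assert h[c] == pytest.approx(kw_h(values[:, c], labels))
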
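import numpy as np
import pytest
from scipy import stats

from swangtest.core import (
    InvalidDesignError,
    MomentDesign,
    deviation_matrix,
    generalized_inverse,
    power_matrix,
    run_swang,
    swang_pvalue,
    swang_statistic,
    swang_statistic_stack,
)
from swangtest.moments import UndefinedMomentError

from conftest import make_matrix


def brute_force_hotelling_f(x, y, orders):
    """Independent oracle: two-sample Hotelling F on moment vectors,
    written with explicit loops and a plain matrix inverse."""
    n, m = len(x), len(y)
    k = len(orders)
    vx = np.array([[xi ** r for xi in x] for r in orders], dtype=float)
    vy = np.array([[yi ** r for yi in y] for r in orders], dtype=float)
    xbar = vx.sum(axis=1) / n
    ybar = vy.sum(axis=1) / m
    S = np.zeros((k, k))
    for j in range(n):
        d = vx[:, j] - xbar
        S += np.outer(d, d)
    for j in range(m):
        d = vy[:, j] - ybar
        S += np.outer(d, d)
    S /= n + m - 2
    diff = xbar - ybar
    tsq = (n * m / (n + m)) * diff @ np.linalg.inv(S) @ diff
    f = (n + m - k - 1) / ((n + m - 2) * k) * tsq
    return f, stats.f.sf(f, k, n + m - k - 1)


class TestMomentDesign:
    def test_range_shorthand(self):
        d = MomentDesign.from_range(1, 4)
        assert d.orders == (1, 2, 3, 4)
        assert d.k_dim == 4
        assert d.is_contiguous_from_one
        assert str(d) == "SWang(1,4)"

    def test_explicit_orders(self):
        d = MomentDesign((1, 3, 5), max_order=5)
        assert not d.is_contiguous_from_one
        assert str(d) == "SWang((1,3,5))"

    def test_invalid_designs(self):
        with pytest.raises(InvalidDesignError):
            MomentDesign((2, 1))
        with pytest.raises(InvalidDesignError):
            MomentDesign((0, 1))
        with pytest.raises(InvalidDesignError):
            MomentDesign((1, 5))  # above the default cap of 4
        MomentDesign((1, 5), max_order=5)  # explicit override allowed


class TestPowerAndDeviation:
    def test_power_matrix_examples(self):
        np.testing.assert_allclose(
            power_matrix([1, 2], MomentDesign.from_range(1, 2)), [[1, 2], [1, 4]]
        )
        np.testing.assert_allclose(
            power_matrix([-1], MomentDesign.from_range(1, 3)), [[-1], [1], [-1]]
        )
        np.testing.assert_allclose(
            power_matrix([0.5, 2.0], MomentDesign.from_range(1, 4)),
            [[0.5, 2], [0.25, 4], [0.125, 8], [0.0625, 16]],
        )

    def test_power_matrix_overflow(self):
        with pytest.raises(UndefinedMomentError):
            power_matrix([1e200, 2.0], MomentDesign.from_range(1, 4))

    def test_deviation_matrix_examples(self):
        # single order 1: scalar scatter sum (x - mean)^2
        np.testing.assert_allclose(deviation_matrix([[1.0, 3.0]]), [[2.0]])
        np.testing.assert_allclose(
            deviation_matrix([[4.0, 4.0, 4.0], [2.0, 2.0, 2.0]]), np.zeros((2, 2))
        )
        P = power_matrix([1, 2, 4], MomentDesign.from_range(1, 2))
        D = deviation_matrix(P)
        assert D[0, 0] == pytest.approx(14.0 / 3.0)  # sum (x - 7/3)^2
        np.testing.assert_allclose(D, D.T)

    def test_generalized_inverse(self, rng):
        np.testing.assert_allclose(generalized_inverse(np.eye(3)), np.eye(3))
        np.testing.assert_allclose(
            generalized_inverse(np.ones((2, 2))), 0.25 * np.ones((2, 2))
        )
        A = rng.standard_normal((4, 4))
        M = A @ A.T + 0.5 * np.eye(4)  # nonsingular SPD
        np.testing.assert_allclose(M @ generalized_inverse(M), np.eye(4), atol=1e-8)
        with pytest.raises(ValueError):
            generalized_inverse(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestSwangStatistic:
    def test_identical_groups_null(self):
        x = [1.0, 2.5, 3.0, 4.0, 5.5]
        r = swang_statistic(x, x, (1, 4))
        assert r.statistic == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == pytest.approx(1.0, abs=1e-10)

    def test_single_moment_is_squared_t(self, rng):
        """SWang(1,1) equals the squared pooled t with matching p."""
        for _ in range(50):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.3, 1, 5)
            r = swang_statistic(x, y, (1, 1))
            t, p = stats.ttest_ind(x, y, equal_var=True)
            assert r.statistic == pytest.approx(t ** 2, abs=1e-10, rel=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_brute_force_hotelling(self, rng):
        """Pooled Hotelling-F oracle on (value, value^2) vectors, 6 vs 6."""
        for _ in range(25):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            r = swang_statistic(x, y, (1, 2))
            f_oracle, p_oracle = brute_force_hotelling_f(x, y, (1, 2))
            assert r.statistic == pytest.approx(f_oracle, rel=1e-8)
            assert r.p_value == pytest.approx(p_oracle, rel=1e-8, abs=1e-12)

    def test_pinv_equals_solve_path(self, rng):
        for _ in range(25):
            x = rng.normal(5, 2, 8)
            y = rng.normal(5, 2, 7)
            a = swang_statistic(x, y, (1, 4), inverse="pinv")
            b = swang_statistic(x, y, (1, 4), inverse="solve")
            assert a.statistic == pytest.approx(b.statistic, rel=1e-8)

    def test_affine_invariance(self, rng):
        """Common shift/scale of both groups leaves the statistic unchanged
        for contiguous designs 1..k."""
        x = rng.normal(7, 1.5, 6)
        y = rng.normal(7, 1.5, 8)
        base = swang_statistic(x, y, (1, 4)).statistic
        for a, b in [(2.0, 0.0), (0.5, 3.0), (-1.0, 10.0), (10.0, -40.0)]:
            r = swang_statistic(a * x + b, a * y + b, (1, 4))
            assert r.statistic == pytest.approx(base, rel=1e-8)

    def test_pvalue_properties(self):
        assert swang_pvalue(0.0, 5, 5, 4) == pytest.approx(1.0)
        p1 = swang_pvalue(1.0, 5, 5, 4)
        p2 = swang_pvalue(2.0, 5, 5, 4)
        assert p2 < p1  # monotone survival function
        # t / F identity at k_dim = 1
        t = 1.7
        assert swang_pvalue(t ** 2, 5, 5, 1) == pytest.approx(
            2 * stats.t.sf(t, 8), rel=1e-12
        )
        with pytest.raises(InvalidDesignError):
            swang_pvalue(1.0, 3, 2, 4)

    def test_size_rule_enforced(self):
        with pytest.raises(InvalidDesignError, match="greater"):
            swang_statistic([1, 2, 3], [1, 2, 3], MomentDesign((1, 2, 3, 4, 5), max_order=5))
        with pytest.raises(InvalidDesignError):
            swang_statistic([1.0], [1, 2, 3], (1, 1))

    def test_degenerate_constant_groups(self):
        r = swang_statistic([3.0, 3.0, 3.0], [3.0, 3.0, 3.0], (1, 2))
        assert r.p_value == 1.0
        assert r.flag is not None


class TestStackAndRunner:
    def test_stack_matches_scalar(self, rng):
        X = rng.normal(1, 1.5, (30, 5))
        Y = rng.normal(1, 1.5, (30, 6))
        stat, p, _ = swang_statistic_stack(X, Y, (1, 4))
        for i in range(0, 30, 7):
            r = swang_statistic(X[i], Y[i], (1, 4))
            assert stat[i] == pytest.approx(r.statistic, rel=1e-10)
            assert p[i] == pytest.approx(r.p_value, rel=1e-10)

    def test_null_matrix_calibration(self, rng):
        """~5% of null genes at p <= 0.05, within binomial 95% bounds."""
        mat = make_matrix(rng.normal(1, 1.5, (100, 20)), 10, 10)
        res = run_swang(mat, (1, 4), alpha=0.05)
        n_called = int(res["call"].sum())
        lo, hi = stats.binom.ppf([0.025, 0.975], 100, 0.05)
        assert lo <= n_called <= hi + 1

    def test_constant_gene_flagged_not_fatal(self, rng):
        values = np.vstack([np.full(10, 2.0), rng.normal(0, 1, 10)])
        mat = make_matrix(values, 5, 5)
        res = run_swang(mat, (1, 4))
        row = res[res.gene_id == "g0"].iloc[0]
        assert row.p_value == 1.0
        assert row.flag == "degenerate"
        assert len(res) == 2

    def test_bh_adjustment_column(self, rng):
        mat = make_matrix(rng.normal(0, 1, (50, 10)), 5, 5)
        res = run_swang(mat, (1, 2), adjust="bh")
        assert "adj_p" in res.columns
        assert (res.adj_p >= res.p_value - 1e-12).all()
        expected = stats.false_discovery_control(res.p_value.to_numpy(), method="bh")
        np.testing.assert_allclose(res.adj_p.to_numpy(), expected)
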
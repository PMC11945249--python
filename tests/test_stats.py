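import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from enzvec.errors import DomainError, InputError
from enzvec.stats import (
    SalinityClass,
    class_anova,
    classify_salinity,
    loglinear_fit,
    mrm,
    partial_regression,
    variance_partition,
    vif_filter,
    zscore,
)


class TestClassifySalinity:
    @pytest.mark.parametrize(
        "sal,expected",
        [
            (0.13, SalinityClass.FRESHWATER),
            (0.49, SalinityClass.FRESHWATER),
            (0.5, SalinityClass.SUBSALINE),  # left-closed boundary
            (2.99, SalinityClass.SUBSALINE),
            (3.0, SalinityClass.HYPOSALINE),
            (19.99, SalinityClass.HYPOSALINE),
            (20.0, SalinityClass.MESOSALINE),
            (31.06, SalinityClass.MESOSALINE),
        ],
    )
    def test_boundaries(self, sal, expected):
        assert classify_salinity(sal) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            classify_salinity(0.0)

    def test_ordered_piecewise_constant(self):
        order = ["FRESHWATER", "SUBSALINE", "HYPOSALINE", "MESOSALINE"]
        grid = np.linspace(0.01, 40, 2000)
        ranks = [order.index(classify_salinity(s).value) for s in grid]
        assert ranks == sorted(ranks)


class TestLoglinearFit:
    def test_identity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        res = loglinear_fit(x, x)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        res = loglinear_fit([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert res.slope == 0.0
        assert res.adj_r2 <= 0.0

    def test_power_law_exact(self, rng):
        x = rng.uniform(0.5, 50.0, size=40)
        y = 2.7 * x**-1.4
        res = loglinear_fit(x, y)
        assert res.slope == pytest.approx(-1.4, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            loglinear_fit([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_variance_x(self):
        with pytest.raises(DomainError):
            loglinear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_adj_r2_formula(self, rng):
        x = rng.uniform(1, 10, size=30)
        y = x ** 1.5 * np.exp(rng.normal(0, 0.3, size=30))
        res = loglinear_fit(x, y)
        r = np.corrcoef(np.log(x), np.log(y))[0, 1]
        expected = 1 - (1 - r**2) * (30 - 1) / (30 - 2)
        assert res.adj_r2 == pytest.approx(expected, abs=1e-12)


class TestClassAnova:
    def test_identical_values_null(self):
        res = class_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert res.letters["a"] == res.letters["b"]

    def test_separated_groups(self, rng):
        vals = np.concatenate([rng.normal(0, 1e-3, 5), 10 + rng.normal(0, 1e-3, 5)])
        res = class_anova(vals, ["lo"] * 5 + ["hi"] * 5)
        assert res.p_value < 1e-6
        assert res.letters["lo"] != res.letters["hi"]

    def test_simulation_oracle_third_group_separate(self):
        # N(0,1), N(0,1), N(5,1), n=30 each: only the shifted group separates
        rng = np.random.default_rng(42)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                               rng.normal(5, 1, 30)])
        cls = ["g1"] * 30 + ["g2"] * 30 + ["g3"] * 30
        res = class_anova(vals, cls)
        assert res.letters["g1"] == res.letters["g2"]
        assert res.letters["g3"] != res.letters["g1"]

    def test_small_class_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            res = class_anova([1.0, 2.0, 1.5, 2.5, 9.0],
                              ["a", "a", "b", "b", "tiny"])
        assert res.dropped_classes == ("tiny",)
        assert "tiny" not in res.class_means

    def test_needs_two_classes(self):
        with pytest.raises(DomainError):
            class_anova([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestPartialRegression:
    def test_independence_limit(self, rng):
        n = 3000
        x = np.exp(rng.normal(0, 1, n))
        y = x ** 0.8 * np.exp(rng.normal(0, 0.5, n))
        control = np.exp(rng.normal(0, 1, n))  # unrelated
        marginal = loglinear_fit(x, y).adj_r2
        partial = partial_regression(y, x, control).adj_r2
        assert partial == pytest.approx(marginal, abs=0.02)

    def test_full_confounding(self, rng):
        n = 500
        control = np.exp(rng.normal(0, 1, n))
        y = control ** 1.3  # exact function of control
        x = np.exp(rng.normal(0, 1, n))
        assert partial_regression(y, x, control).adj_r2 == pytest.approx(0.0, abs=0.01)

    def test_equals_squared_partial_correlation(self, rng):
        # closed-form oracle from the correlation matrix
        n = 2000
        c = rng.normal(0, 1, n)
        x = 0.6 * c + rng.normal(0, 0.8, n)
        y = 0.5 * c - 0.4 * x + rng.normal(0, 0.7, n)
        ey, ex, ec = np.exp(y), np.exp(x), np.exp(c)
        res = partial_regression(ey, ex, ec)
        raw_r2 = 1 - (1 - res.adj_r2) * (n - 2) / (n - 1)
        r = np.corrcoef(np.vstack([y, x, c]))
        r_partial = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
        )
        assert raw_r2 == pytest.approx(r_partial**2, abs=1e-6)

    def test_x_function_of_control_rejected(self):
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(DomainError):
            partial_regression(c * 2, c**2, c)


class TestVariancePartition:
    def test_orthogonal_blocks(self):
        rng = np.random.default_rng(7)
        n = 4000
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        y = 1.0 * a + 0.7 * b + 0.4 * c + rng.normal(0, 1, n)
        res = variance_partition(y, a, b, c)
        marg_a = 1.0 / (1 + 0.49 + 0.16 + 1)
        assert res.pure_a == pytest.approx(marg_a, abs=0.03)
        for shared in (res.shared_ab, res.shared_ac, res.shared_bc, res.shared_abc):
            assert shared == pytest.approx(0.0, abs=0.03)

    def test_duplicated_block_shares(self):
        rng = np.random.default_rng(8)
        n = 500
        a = rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        y = a + rng.normal(0, 1, n)
        res = variance_partition(y, a, a.copy(), c)
        assert res.pure_a == pytest.approx(0.0, abs=1e-9)
        assert res.pure_b == pytest.approx(0.0, abs=1e-9)
        assert res.shared_ab > 0.2

    def test_null_simulation_oracle(self):
        rng = np.random.default_rng(9)
        n = 200
        y = rng.normal(0, 1, n)
        res = variance_partition(
            y, rng.normal(0, 1, n), rng.normal(0, 1, n), rng.normal(0, 1, n)
        )
        for frac in (res.pure_a, res.pure_b, res.pure_c, res.shared_ab,
                     res.shared_ac, res.shared_bc, res.shared_abc):
            assert abs(frac) < 0.05
        assert res.residual == pytest.approx(1.0, abs=0.05)

    def test_fractions_sum_to_one(self, rng):
        n = 300
        blocks = [rng.normal(0, 1, (n, 2)) for _ in range(3)]
        y = blocks[0] @ [1, -1] + blocks[1][:, 0] + rng.normal(0, 1, n)
        res = variance_partition(y, *blocks)
        assert sum(res.fractions().values()) == pytest.approx(1.0, abs=1e-9)

    def test_raw_r2_monotone_under_nesting(self, rng):
        # raw (not adjusted) R² cannot decrease when predictors are added
        from enzvec.stats import _ols_r2

        n = 150
        y = rng.normal(0, 1, n)
        a = rng.normal(0, 1, (n, 2))
        ab = np.column_stack([a, rng.normal(0, 1, (n, 2))])
        r2_a, _ = _ols_r2(y, a, "a")
        r2_ab, _ = _ols_r2(y, ab, "ab")
        assert r2_ab >= r2_a - 1e-12

    def test_response_zero_variance(self):
        with pytest.raises(DomainError):
            variance_partition(np.ones(50), np.arange(50.0), np.arange(50.0) ** 2,
                               np.random.default_rng(0).normal(size=50))


def _random_distance(rng, n=12, dim=2):
    return squareform(pdist(rng.standard_normal((n, dim))))


class TestMrm:
    def test_identity(self, rng):
        d = _random_distance(rng)
        res = mrm(d, [d], n_perm=199, seed=0)
        assert res.coefficients["x1"] == pytest.approx(1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.p_values["x1"] == pytest.approx(1 / 200)

    def test_reproducible_given_seed(self, rng):
        d = _random_distance(rng)
        p = _random_distance(rng)
        r1 = mrm(d, [p], n_perm=199, seed=11)
        r2 = mrm(d, [p], n_perm=199, seed=11)
        assert r1 == r2

    def test_duplicate_predictors_warn(self, rng):
        d = _random_distance(rng)
        p = _random_distance(rng)
        with pytest.warns(UserWarning, match="collinear"):
            mrm(d, [p, p.copy()], n_perm=99, seed=0)

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InputError, match="symmetric"):
            mrm(m, [np.zeros((2, 2))], n_perm=99)

    def test_nan_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(InputError, match="NaN"):
            mrm(m, [np.zeros((3, 3))], n_perm=99)

    def test_min_permutations(self, rng):
        d = _random_distance(rng)
        with pytest.raises(InputError):
            mrm(d, [d], n_perm=10)


class TestVifFilter:
    def test_orthogonal_untouched(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (200, 4)), columns=list("abcd"))
        retained, dropped = vif_filter(df)
        assert retained == list("abcd")
        assert dropped == {}

    def test_exact_collinearity(self, rng):
        x1 = rng.normal(0, 1, 100)
        df = pd.DataFrame({"x1": x1, "x2": 2 * x1, "z": rng.normal(0, 1, 100)})
        retained, dropped = vif_filter(df)
        assert "x2" in dropped  # later-alphabetical of the tied pair drops first
        assert "x1" in retained and "z" in retained

    def test_high_correlation_oracle(self):
        # direct VIF from the correlation-matrix inverse as the oracle
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 400)
        cols = {f"p{i}": base + rng.normal(0, 0.1, 400) for i in range(3)}
        df = pd.DataFrame(cols)
        corr = np.corrcoef(df.to_numpy().T)
        oracle_vifs = np.diag(np.linalg.inv(corr))
        assert oracle_vifs.max() > 10
        retained, dropped = vif_filter(df)
        assert len(dropped) >= 1
        assert len(retained) + len(dropped) == 3

    def test_needs_multiple_predictors(self):
        with pytest.raises(InputError):
            vif_filter(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestZscore:
    def test_closed_form(self):
        assert zscore([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        z = zscore(rng.normal(3, 7, 100))
        assert zscore(z) == pytest.approx(z, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DomainError):
            zscore([2.0, 2.0, 2.0])

    def test_moments(self, rng):
        z = zscore(rng.uniform(0, 5, 50))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)
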
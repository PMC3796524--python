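"""Two-block PLS, RV coefficient, permutation tests, allometric regression."""

import numpy as np
import pytest

from murimorph.association import (
    permutation_test,
    rv_coefficient,
    shape_size_regression,
    two_block_pls,
)


class TestTwoBlockPLS:
    def test_identical_blocks_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 5))
        res = two_block_pls(x, x)
        assert res.axis_correlation[0] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_univariate_blocks_give_pearson_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = 0.6 * x + 0.8 * rng.normal(size=80)
        res = two_block_pls(x, y)
        assert res.axis_correlation[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)
        assert res.percent_covariation[0] == pytest.approx(100.0)

    def test_single_column_block2_single_axis(self):
        rng = np.random.default_rng(2)
        res = two_block_pls(rng.normal(size=(50, 7)), rng.normal(size=50))
        assert res.singular_values.size == 1
        assert res.percent_covariation[0] == pytest.approx(100.0)

    def test_first_singular_value_dominates_random_probes(self):
        """SVD optimality: no random unit-projection pair beats the first axis."""
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=(60, 6))
        x2 = rng.normal(size=(60, 4)) + 0.5 * x1[:, :4]
        res = two_block_pls(x1, x2, mode="covariance")
        x1c = x1 - x1.mean(axis=0)
        x2c = x2 - x2.mean(axis=0)
        best = 0.0
        for _ in range(1000):
            u = rng.normal(size=6)
            u /= np.linalg.norm(u)
            v = rng.normal(size=4)
            v /= np.linalg.norm(v)
            best = max(best, abs((x1c @ u) @ (x2c @ v) / (len(x1) - 1)))
        assert res.singular_values[0] >= best - 1e-12

    def test_zero_variance_column_rejected_in_correlation_mode(self):
        x = np.random.default_rng(4).normal(size=(20, 3))
        x[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            two_block_pls(x, np.arange(20.0))

    def test_matches_sklearn_plssvd(self):
        """Cross-check axes against scikit-learn's PLSSVD on the same blocks."""
        from sklearn.cross_decomposition import PLSSVD

        rng = np.random.default_rng(5)
        x1 = rng.normal(size=(70, 5))
        x2 = 0.4 * x1[:, :3] + rng.normal(size=(70, 3))
        ours = two_block_pls(x1, x2, mode="covariance")
        ref = PLSSVD(n_components=1, scale=False).fit(x1, x2)
        u_ref = ref.x_weights_[:, 0]
        sign = np.sign(u_ref @ ours.left_vectors[:, 0])
        assert np.allclose(ours.left_vectors[:, 0] * sign, u_ref, atol=1e-8)


class TestRV:
    def test_self_and_rotation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert rv_coefficient(x, x) == pytest.approx(1.0)
        assert rv_coefficient(x, x @ q) == pytest.approx(1.0, abs=1e-10)

    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(7)
        rv = rv_coefficient(rng.normal(size=(500, 5)), rng.normal(size=(500, 5)))
        assert rv < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rv_coefficient(np.ones((5, 2)), np.arange(10.0).reshape(5, 2))


class TestPermutation:
    def test_floor_under_perfect_association(self):
        x = np.linspace(0, 1, 30)
        p = permutation_test(lambda a, b: abs(np.corrcoef(a[:, 0], b[:, 0])[0, 1]), x, x, n_perm=9999, seed=0)
        assert p == pytest.approx(1e-4)

    def test_single_permutation_two_outcomes(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        p = permutation_test(rv_coefficient, x, rng.normal(size=20), n_perm=1, seed=1)
        assert p in (0.5, 1.0)

    def test_rejects_zero_permutations(self):
        with pytest.raises(ValueError):
            permutation_test(rv_coefficient, np.zeros(5), np.zeros(5), n_perm=0)


class TestRegression:
    def test_exact_linear_dependence(self):
        x = np.linspace(-1, 1, 40)
        y = np.outer(x, [1.0, -2.0, 0.5])
        res = shape_size_regression(y, x)
        assert res.percent_variance_predicted == pytest.approx(100.0, abs=1e-8)
        assert res.wilks_lambda < 1e-12

    def test_null_predictor_explains_little(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(600, 4))
        res = shape_size_regression(y, rng.normal(size=600))
        assert res.percent_variance_predicted < 1.5
        assert res.p_value > 0.01

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            shape_size_regression(np.zeros((10, 2)), np.ones(10))

    def test_rank_guard_flags(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(10, 20))
        with pytest.warns(UserWarning):
            res = shape_size_regression(y, rng.normal(size=10))
        assert res.rank_deficient
        assert res.n_components <= 8

    def test_wilks_matches_statsmodels(self):
        """Cross-check Wilks' lambda and its p-value against statsmodels MANOVA."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        y = np.outer(x, [0.5, -0.2, 0.1]) + rng.normal(size=(50, 3))
        ours = shape_size_regression(y, x)
        mv = MANOVA(endog=y, exog=np.column_stack([np.ones(50), x]))
        table = mv.mv_test().results["x1"]["stat"]
        assert ours.wilks_lambda == pytest.approx(table.loc["Wilks' lambda", "Value"], abs=1e-8)
        assert ours.p_value == pytest.approx(table.loc["Wilks' lambda", "Pr > F"], abs=1e-8)
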
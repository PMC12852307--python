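"""Tests for the discrepancy emulator: weights, lasso selection, additivity."""

import numpy as np
import pytest

import cohortgp as cg
from cohortgp.discrepancy import (
    DiscrepancyPredictive,
    _OutputDiscrepancy,
    _lasso_path_fit,
)
from cohortgp.errors import ArgumentError, BudgetError, RankError, ShapeError, StateError
from cohortgp.gp import PosteriorPrediction


class _StubGP:
    """Duck-typed emulator returning fixed mean/variance at any query."""

    def __init__(self, mean, var):
        self._m, self._v = float(mean), float(var)

    def predict(self, queries, *, full_covariance=False, include_noise=False):
        q = np.atleast_2d(queries).shape[0]
        cov = self._v * np.eye(q) if full_covariance else None
        return PosteriorPrediction(
            np.atleast_2d(queries), np.full(q, self._m), np.full(q, self._v), cov
        )


class TestReferenceMeans:
    def test_delegates_to_each_reference(self, refs_small, small_cohort):
        gps = [refs_small.member(mid)["y0"] for mid in refs_small.member_ids]
        Q = np.random.default_rng(0).uniform(0, 1, (6, 2))
        M = cg.reference_means(gps, Q)
        assert M.shape == (6, 5)
        for i, gp in enumerate(gps):
            assert np.array_equal(M[:, i], gp.predict(Q).mean)
        # permuting the reference order permutes columns only
        Mp = cg.reference_means(gps[::-1], Q)
        assert np.array_equal(Mp, M[:, ::-1])

    def test_empty_reference_list_raises(self):
        with pytest.raises(StateError):
            cg.reference_means([], np.zeros((2, 2)))


class TestResiduals:
    def test_zero_weights_return_raw_outputs(self):
        y = np.array([1.0, 2.0, 3.0])
        M = np.random.default_rng(0).normal(size=(3, 4))
        w = cg.WeightVector(np.zeros(4), "fixed")
        assert np.array_equal(cg.compute_residuals(y, M, w), y)

    def test_exact_weighted_sum_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(10, 3))
        a = np.array([0.5, -1.2, 2.0])
        w = cg.WeightVector(a, "fixed")
        assert np.max(np.abs(cg.compute_residuals(M @ a, M, w))) < 1e-10

    def test_random_instance_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(2)
        y, M, a = rng.normal(size=7), rng.normal(size=(7, 4)), rng.normal(size=4)
        got = cg.compute_residuals(y, M, cg.WeightVector(a, "fixed"))
        want = np.array([y[j] - sum(a[i] * M[j, i] for i in range(4)) for j in range(7)])
        assert np.allclose(got, want, atol=1e-12)

    def test_misaligned_rows_raise(self):
        with pytest.raises(ShapeError):
            cg.compute_residuals(np.zeros(3), np.zeros((4, 2)), cg.WeightVector(np.zeros(2), "fixed"))


class TestLasso:
    def test_huge_lambda_shrinks_everything_to_zero(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(30, 5))
        y = M @ np.array([1.0, 0.5, 0.0, 0.0, -0.3])
        w = cg.learn_weights_lasso(y, M, lambda_grid=np.array([1e9]))
        assert w.support.size == 0

    def test_copy_of_reference_recovers_unit_weight(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(40, 6))
        y = M[:, 3] + 1e-8 * rng.normal(size=40)
        w = cg.learn_weights_lasso(y, M, seed=0)
        assert list(w.support) == [3]
        assert abs(w.values[3] - 1.0) < 1e-2

    def test_zero_lambda_equals_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(25, 4))
        y = M @ np.array([0.7, -0.2, 1.1, 0.4]) + 0.05 * rng.normal(size=25)
        w = cg.learn_weights_lasso(y, M, lambda_grid=np.array([0.0]))
        ols = np.linalg.solve(M.T @ M, M.T @ y)
        assert np.allclose(w.values, ols, atol=1e-6)

    def test_support_size_non_increasing_in_lambda(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(30, 8))
        y = M @ np.array([1.0, 0.8, 0.0, 0.3, 0.0, 0.0, -0.5, 0.1]) + 0.1 * rng.normal(size=30)
        sizes = []
        for lam in np.geomspace(1e-3, 1e3, 15):
            a = _lasso_path_fit(M, y, lam)
            sizes.append(int(np.sum(np.abs(a) > 1e-6)))
        assert all(s1 >= s2 for s1, s2 in zip(sizes, sizes[1:]))

    def test_empty_grid_and_zero_predictors(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(10, 2))
        with pytest.raises(ArgumentError):
            cg.learn_weights_lasso(M[:, 0], M, lambda_grid=np.array([]))
        with pytest.warns(UserWarning):
            w = cg.learn_weights_lasso(rng.normal(size=10), np.zeros((10, 2)))
        assert np.array_equal(w.values, np.zeros(2))


class TestLeastSquaresWeight:
    def test_exact_proportionality(self):
        g = np.random.default_rng(8).normal(size=12)
        assert abs(cg.learn_weight_least_squares(2.0 * g, g).values[0] - 2.0) < 1e-12

    def test_orthogonal_vectors_give_zero(self):
        g = np.array([1.0, -1.0, 1.0, -1.0])
        f = np.array([1.0, 1.0, -1.0, -1.0])
        assert abs(cg.learn_weight_least_squares(f, g).values[0]) < 1e-12

    def test_random_instance_matches_dot_product_oracle(self):
        rng = np.random.default_rng(9)
        f, g = rng.normal(size=20), rng.normal(size=20)
        got = cg.learn_weight_least_squares(f, g).values[0]
        assert abs(got - (g @ f) / (g @ g)) < 1e-12

    def test_zero_predictor_raises(self):
        with pytest.raises(RankError):
            cg.learn_weight_least_squares(np.ones(5), np.zeros(5))


class TestCombinedPosterior:
    def test_additivity_arithmetic_oracle(self):
        """refs (2.0, 3.0)/(0.1, 0.2), a=(0.5,0.5), delta (0.1, 0.05)
        -> combined mean 2.6, combined variance 0.125."""
        od = _OutputDiscrepancy(
            references=[_StubGP(2.0, 0.1), _StubGP(3.0, 0.2)],
            weights=cg.WeightVector(np.array([0.5, 0.5]), "fixed"),
            delta=_StubGP(0.1, 0.05),
        )
        p = DiscrepancyPredictive(od).predict(np.zeros((1, 2)))
        assert abs(p.mean[0] - 2.6) < 1e-12
        assert abs(p.variance[0] - 0.125) < 1e-12

    def test_zero_weights_reduce_to_delta_posterior(self):
        od = _OutputDiscrepancy(
            references=[_StubGP(5.0, 1.0)],
            weights=cg.WeightVector(np.array([0.0]), "fixed"),
            delta=_StubGP(0.7, 0.2),
        )
        p = DiscrepancyPredictive(od).predict(np.zeros((3, 2)))
        assert np.allclose(p.mean, 0.7) and np.allclose(p.variance, 0.2)

    def test_degenerate_delta_passes_reference_through(self):
        od = _OutputDiscrepancy(
            references=[_StubGP(4.0, 0.3), _StubGP(-1.0, 9.0)],
            weights=cg.WeightVector(np.array([1.0, 0.0]), "fixed"),
            delta=_StubGP(0.0, 0.0),
        )
        p = DiscrepancyPredictive(od).predict(np.zeros((2, 2)))
        assert np.allclose(p.mean, 4.0) and np.allclose(p.variance, 0.3)

    def test_additivity_invariant_on_fitted_emulator(self, het_cohort, refs_het, fast_opt):
        new = cg.make_linear_member(het_cohort, np.eye(10)[2], 0.3, n_sims=40, seed=1)
        em = cg.train_discrepancy(new, refs_het, "lasso_fixed", m=25, seed=0,
                                  optimizer_config=fast_opt)
        Q = np.random.default_rng(3).uniform(0, 1, (8, 2))
        od = em.per_output["y0"]
        combined = em.predictive("y0").predict(Q)
        ref_part = sum(
            a**2 * r.predict(Q).variance for a, r in zip(od.weights.values, od.references) if a
        )
        delta_var = od.delta.predict(Q).variance
        assert np.allclose(combined.variance - ref_part, delta_var, atol=1e-10)

    def test_monte_carlo_consistency(self, het_cohort, refs_het, fast_opt):
        """Sampling references and delta independently and summing matches the
        analytic combined posterior within Monte-Carlo error."""
        new = cg.make_linear_member(het_cohort, np.eye(10)[1], 0.3, n_sims=40, seed=2)
        em = cg.train_discrepancy(new, refs_het, "lasso_fixed", m=25, seed=0,
                                  optimizer_config=fast_opt)
        q = np.random.default_rng(4).uniform(0, 1, (1, 2))
        od = em.per_output["y0"]
        n = 10_000
        total = od.delta.sample(q, n, seed=100, joint=False)[:, 0]
        for i, (a, r) in enumerate(zip(od.weights.values, od.references)):
            if a:
                total = total + a * r.sample(q, n, seed=200 + i, joint=False)[:, 0]
        p = em.predictive("y0").predict(q)
        se_mean = np.sqrt(p.variance[0] / n)
        assert abs(total.mean() - p.mean[0]) < 3 * se_mean
        assert abs(total.var() - p.variance[0]) < 3 * p.variance[0] * np.sqrt(2.0 / n) + 1e-12


class TestTrainDiscrepancy:
    def test_unknown_strategy_and_empty_cohort(self, het_cohort, refs_het):
        new = cg.make_linear_member(het_cohort, np.eye(10)[0], 0.0, n_sims=20, seed=0)
        with pytest.raises(ArgumentError):
            cg.train_discrepancy(new, refs_het, "bogus")
        empty = cg.IndividualCohortEmulators({}, {})
        with pytest.raises(StateError):
            cg.train_discrepancy(new, empty, "fixed_one")
        with pytest.raises(BudgetError):
            cg.train_discrepancy(new, refs_het, "fixed_one", m=10_000)

    def test_single_reference_strategies_have_singleton_support(self, het_cohort, refs_het, fast_opt):
        new = cg.make_linear_member(het_cohort, np.eye(10)[5], 0.2, n_sims=40, seed=3)
        for strat in ("fixed_one", "single_ls", "single_hyper"):
            em = cg.train_discrepancy(new, refs_het, strat, m=20, seed=4,
                                      optimizer_config=fast_opt)
            assert em.weights("y0").support.size <= 1

    def test_zero_discrepancy_member_gives_flat_delta_and_high_r2(self, het_cohort, refs_het, fast_opt):
        """New member identical to its reference: delta stays near zero and the
        combined emulator is accurate with only 5 training points."""
        new = cg.make_linear_member(het_cohort, np.eye(10)[3], 0.0, n_sims=40, seed=5)
        single = cg.IndividualCohortEmulators(
            {"member_03": refs_het.member("member_03")}, {}
        )
        em = cg.train_discrepancy(new, single, "fixed_one", m=5, seed=6,
                                  optimizer_config=fast_opt)
        assert em.weights("y0").values[0] == 1.0
        grid = cg.latin_hypercube(50, 2, seed=9)
        dmean = em.per_output["y0"].delta.predict(grid).mean
        assert np.max(np.abs(dmean)) < 0.05 * new.outputs[:, 0].std()
        r2, _ = cg.posterior_r_squared(
            em.predictive("y0"), new.design[5:], new.outputs[5:, 0], n_samples=200, seed=1
        )
        assert r2 > 0.99

    def test_all_zero_weights_reduce_to_individual_emulator(self, het_cohort, refs_het, fast_opt):
        """Forcing every weight to zero must reproduce a plain GP on the same rows."""
        new = cg.make_linear_member(het_cohort, np.zeros(10), 1.0, n_sims=30, seed=7)
        em = cg.train_discrepancy(new, refs_het, "lasso_fixed", m=None, seed=8,
                                  lambda_grid=np.array([1e12]), optimizer_config=fast_opt)
        assert em.weights("y0").support.size == 0
        direct = cg.fit_gp(new.design, new.outputs[:, 0], optimizer_config=fast_opt, seed=8)
        Q = np.random.default_rng(10).uniform(0, 1, (6, 2))
        a, b = em.predictive("y0").predict(Q), direct.predict(Q)
        assert np.allclose(a.mean, b.mean, atol=1e-6)
        assert np.allclose(a.variance, b.variance, atol=1e-6)

    def test_support_recovery_of_sparse_linear_member(self, het_cohort, refs_het, fast_opt):
        """Lasso-indicator recovers the exact generating support {1,4,7}."""
        w = np.zeros(10)
        w[[1, 4, 7]] = [0.5, 0.3, 0.2]
        new = cg.make_linear_member(het_cohort, w, 0.0, n_sims=60, seed=5, noise_sd=0.0)
        em = cg.train_discrepancy(new, refs_het, "lasso_indicator_hyper", m=20, seed=2,
                                  optimizer_config=fast_opt)
        wv = em.weights("y0")
        assert list(wv.support) == [1, 4, 7]
        assert np.allclose(wv.values[[1, 4, 7]], [0.5, 0.3, 0.2], atol=0.02)
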
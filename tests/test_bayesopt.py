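"""GP surrogate, acquisition functions, escape rule and the full loop."""

import numpy as np
import pytest
from scipy.stats import norm

import voxelopt as vx
from voxelopt.bayesopt import (
    ACQUISITION_NAMES,
    AcquisitionSpec,
    Bounds,
    Observation,
    _candidates,
    estimate_optimum,
    fit_surrogate,
    fit_time_model,
    posterior_predict,
    posterior_surface,
    propose_next,
    run_loop,
)
from voxelopt.errors import ParameterError
from voxelopt.preprocess import PreprocParams

BOUNDS = Bounds((1.0, 15.0), (1.0, 10.0))


def obs(v, f, y, t=1.0):
    return Observation(params=PreprocParams(v, f), y=y, elapsed_s=t)


class _StubPosterior:
    """Duck-typed posterior with fixed mean/sd — for closed-form acquisition
    checks independent of any kernel machinery."""

    def __init__(self, mean, sd, noise_sd=0.1):
        self.mean, self.sd, self.noise_sd = mean, sd, noise_sd

    def predict(self, x):
        n = np.atleast_2d(x).shape[0]
        return np.full(n, self.mean), np.full(n, self.sd)


from conftest import matern52_posterior_oracle


class TestSurrogate:
    def test_single_observation_interpolated(self):
        model = fit_surrogate([obs(5.0, 5.0, 0.3)], BOUNDS)
        mean, _ = posterior_predict(model, PreprocParams(5.0, 5.0))
        assert mean == pytest.approx(0.3, abs=1e-6)

    def test_reverts_to_prior_far_from_data(self):
        model = fit_surrogate(
            [obs(1.2, 1.2, 0.2), obs(1.4, 1.4, 0.4)], BOUNDS,
            optimize_hyperparams=False, length_scale=(0.02, 0.02), noise_level=1e-10,
        )
        mean, sd = posterior_predict(model, PreprocParams(14.5, 9.5))
        assert mean == pytest.approx(model.prior_mean, abs=1e-3)
        prior_sd = np.sqrt(model.gpr.kernel_.k1.k1.constant_value) * model.y_sd
        assert sd == pytest.approx(prior_sd, rel=1e-3)

    def test_three_point_posterior_matches_kernel_matrix_oracle(self):
        model = fit_surrogate(
            [obs(2.0, 3.0, 0.40), obs(8.0, 5.0, 0.25), obs(13.0, 8.0, 0.35)],
            BOUNDS, seed=1,
        )
        queries = np.array([[4.0, 4.0], [9.5, 2.5], [8.0, 5.0], [14.0, 9.0]])
        mean_o, sd_o = matern52_posterior_oracle(model, queries)
        mean_m, sd_m = model.predict(queries)
        np.testing.assert_allclose(mean_m, mean_o, atol=1e-8)
        np.testing.assert_allclose(sd_m, sd_o, atol=1e-8)

    def test_duplicate_observations_handled_by_noise_term(self):
        model = fit_surrogate(
            [obs(5.0, 5.0, 0.3), obs(5.0, 5.0, 0.32), obs(5.0, 5.0, 0.28)], BOUNDS
        )
        mean, sd = posterior_predict(model, PreprocParams(5.0, 5.0))
        assert np.isfinite(mean) and np.isfinite(sd)

    def test_sd_vanishes_at_noise_free_observation(self):
        model = fit_surrogate(
            [obs(3.0, 3.0, 0.2), obs(9.0, 6.0, 0.5), obs(12.0, 2.0, 0.4)],
            BOUNDS, optimize_hyperparams=False, noise_level=1e-10,
        )
        _, sd = posterior_predict(model, PreprocParams(9.0, 6.0))
        assert sd / model.y_sd <= 1e-4

    def test_mirror_symmetric_design_gives_symmetric_sd(self):
        # design is invariant under point reflection about the box center
        model = fit_surrogate(
            [obs(4.0, 3.0, 0.3), obs(8.0, 5.5, 0.3), obs(12.0, 8.0, 0.3)],
            Bounds((1.0, 15.0), (1.0, 10.0)),
            optimize_hyperparams=False, noise_level=1e-6,
        )
        _, sd_a = posterior_predict(model, PreprocParams(6.0, 4.0))
        _, sd_b = posterior_predict(model, PreprocParams(10.0, 7.0))
        assert sd_a == pytest.approx(sd_b, rel=1e-9)

    def test_out_of_bounds_query_rejected(self):
        model = fit_surrogate([obs(5.0, 5.0, 0.3)], BOUNDS)
        with pytest.raises(ParameterError):
            posterior_predict(model, PreprocParams(40.0, 5.0))


class TestAcquisitions:
    def test_zero_sd_no_improvement_gives_zero_ei_and_pi(self):
        stub = _StubPosterior(mean=0.5, sd=0.0)
        x = np.zeros((1, 2))
        assert vx.acquisition_value(stub, x, AcquisitionSpec("ei"), best_y=0.4)[0] == 0.0
        assert vx.acquisition_value(stub, x, AcquisitionSpec("pi"), best_y=0.4)[0] == 0.0

    def test_vanishing_sd_with_unit_improvement_gives_unit_ei(self):
        stub = _StubPosterior(mean=-0.6, sd=1e-12)
        val = vx.acquisition_value(stub, np.zeros((1, 2)), AcquisitionSpec("ei"), best_y=0.4)
        assert val[0] == pytest.approx(1.0, abs=1e-9)

    def test_ei_matches_monte_carlo_oracle(self):
        stub = _StubPosterior(mean=0.3, sd=0.2)
        best = 0.25
        val = vx.acquisition_value(stub, np.zeros((1, 2)), AcquisitionSpec("ei"), best_y=best)[0]
        rng = np.random.default_rng(0)
        draws = rng.normal(0.3, 0.2, size=1_000_000)
        imp = np.maximum(best - draws, 0.0)
        mc, se = imp.mean(), imp.std() / 1000.0
        assert abs(val - mc) < 3 * se

    def test_lcb_ranks_by_mean_minus_kappa_sd(self):
        spec = AcquisitionSpec("lcb", exploration_ratio=0.5)
        a = vx.acquisition_value(_StubPosterior(0.5, 0.1), np.zeros((1, 2)), spec, best_y=0.0)[0]
        b = vx.acquisition_value(_StubPosterior(0.45, 0.0), np.zeros((1, 2)), spec, best_y=0.0)[0]
        # kappa = 2 × 0.5 = 1: 0.5 − 0.1 < 0.45 so a ranks higher
        assert a > b

    def test_per_second_divides_by_time_and_rejects_nonpositive(self):
        stub = _StubPosterior(mean=0.1, sd=0.2)
        spec = AcquisitionSpec("ei_per_second")
        x = np.zeros((1, 2))
        plain = vx.acquisition_value(stub, x, AcquisitionSpec("ei"), best_y=0.4)[0]
        halved = vx.acquisition_value(stub, x, spec, best_y=0.4, predicted_time=2.0)[0]
        assert halved == pytest.approx(plain / 2.0)
        with pytest.raises(ParameterError):
            vx.acquisition_value(stub, x, spec, best_y=0.4, predicted_time=0.0)

    def test_ei_nonnegative_and_pi_in_unit_interval_on_random_models(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 8)
            observations = [
                obs(rng.uniform(1, 15), rng.uniform(1, 10), rng.normal()) for _ in range(n)
            ]
            model = fit_surrogate(observations, BOUNDS, optimize_hyperparams=False,
                                  length_scale=rng.uniform(0.05, 1.0, 2))
            q = np.column_stack([rng.uniform(1, 15, 25), rng.uniform(1, 10, 25)])
            best = min(o.y for o in observations)
            ei = vx.acquisition_value(model, q, AcquisitionSpec("ei"), best_y=best)
            pi = vx.acquisition_value(model, q, AcquisitionSpec("pi"), best_y=best)
            assert np.all(ei >= 0)
            assert np.all((pi >= 0) & (pi <= 1))


class TestEscapeRule:
    def test_direct_rule(self):
        stub = _StubPosterior(0.0, 0.0, noise_sd=0.5)
        spec = AcquisitionSpec("ei_plus", exploration_ratio=0.5)
        assert vx.eiplus_escape_check(stub, 0.10, spec) is True
        assert vx.eiplus_escape_check(stub, 0.30, spec) is False

    def test_trigger_sets_nested_in_exploration_ratio(self):
        model = fit_surrogate(
            [obs(2, 2, 0.4), obs(7, 5, 0.2), obs(13, 8, 0.5), obs(7.2, 5.1, 0.22)],
            BOUNDS, seed=0,
        )
        grid = np.column_stack(
            [np.linspace(1, 15, 40), np.tile(np.linspace(1, 10, 8), 5)]
        )
        _, sds = model.predict(grid)
        lo = AcquisitionSpec("ei_plus", exploration_ratio=0.1)
        hi = AcquisitionSpec("ei_plus", exploration_ratio=0.9)
        trig_lo = {i for i, s in enumerate(sds) if vx.eiplus_escape_check(model, s, lo)}
        trig_hi = {i for i, s in enumerate(sds) if vx.eiplus_escape_check(model, s, hi)}
        assert trig_lo <= trig_hi


class TestProposeNext:
    def test_single_candidate_is_returned(self):
        model = fit_surrogate([obs(5, 5, 0.3), obs(10, 7, 0.4)], BOUNDS, seed=0)
        expected = _candidates(BOUNDS, np.random.default_rng(5), 1)[0]
        prop = propose_next(model, AcquisitionSpec("ei"), BOUNDS,
                            np.random.default_rng(5), n_candidates=1)
        assert prop.as_array() == pytest.approx(expected)

    def test_proposals_stay_within_bounds(self):
        rng = np.random.default_rng(11)
        for i in range(25):
            n = rng.integers(2, 7)
            observations = [
                obs(rng.uniform(1, 15), rng.uniform(1, 10), rng.normal()) for _ in range(n)
            ]
            model = fit_surrogate(observations, BOUNDS, optimize_hyperparams=False,
                                  length_scale=rng.uniform(0.05, 0.8, 2))
            spec = AcquisitionSpec(ACQUISITION_NAMES[i % 6])
            prop = propose_next(model, spec, BOUNDS, rng, n_candidates=128,
                                time_model=lambda x: np.full(np.atleast_2d(x).shape[0], 2.0))
            assert BOUNDS.contains(prop)

    def test_proposal_near_global_acquisition_maximum(self):
        model = fit_surrogate(
            [obs(2, 2, 0.5), obs(6, 4, 0.15), obs(10, 8, 0.4),
             obs(13, 3, 0.45), obs(4, 7, 0.3), obs(8, 6, 0.2)],
            BOUNDS, seed=2,
        )
        spec = AcquisitionSpec("ei")
        best = model.incumbent.y
        prop = propose_next(model, spec, BOUNDS, np.random.default_rng(0))
        gx, gy = np.meshgrid(np.linspace(1, 15, 200), np.linspace(1, 10, 200), indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        grid_vals = vx.acquisition_value(model, grid, spec, best_y=best)
        prop_val = vx.acquisition_value(model, prop.as_array()[None, :], spec, best_y=best)[0]
        tol = 1e-3 * max(grid_vals.max() - grid_vals.min(), 1e-12)
        assert prop_val >= grid_vals.max() - tol


class TestEstimateOptimum:
    def test_single_observation_returns_its_params(self):
        model = fit_surrogate([obs(6.0, 4.0, 0.3)], BOUNDS)
        params, _ = estimate_optimum(model, BOUNDS)
        assert params.as_array() == pytest.approx([6.0, 4.0])

    def test_recovers_quadratic_minimum(self):
        truth = np.array([8.0, 5.0])

        def quad(v, f):
            return 0.1 + ((v - truth[0]) / 7.0) ** 2 + ((f - truth[1]) / 4.5) ** 2

        observations = [
            obs(v, f, quad(v, f))
            for v in np.linspace(1, 15, 5)
            for f in np.linspace(1, 10, 5)
        ]
        model = fit_surrogate(observations, BOUNDS, seed=0, noise_level=1e-8)
        params, est_min = estimate_optimum(model, BOUNDS)
        widths = BOUNDS.highs - BOUNDS.lows
        assert np.all(np.abs(params.as_array() - truth) <= 0.05 * widths)
        # the estimate never exceeds the posterior mean on a dense grid
        surf = posterior_surface(model, BOUNDS, (50, 50))
        assert est_min <= surf["mean"].min() + 1e-9

    def test_estimate_always_within_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            observations = [
                obs(rng.uniform(1, 15), rng.uniform(1, 10), rng.normal()) for _ in range(5)
            ]
            model = fit_surrogate(observations, BOUNDS, optimize_hyperparams=False)
            params, _ = estimate_optimum(model, BOUNDS, grid_shape=(25, 25))
            assert BOUNDS.contains(params)


class TestRunLoop:
    def _loop(self, small_cohort, seed, spec=AcquisitionSpec()):
        subjects, _ = small_cohort
        plan = vx.make_plan(subjects, 10, "classification", seed=seed)
        return run_loop(subjects, plan, "classification", BOUNDS, spec,
                        burn_in=3, seed=seed, k=5)

    def test_burn_in_then_guided_phases(self, small_cohort):
        res = self._loop(small_cohort, seed=0)
        phases = [o.phase for o in res.observations]
        assert phases == ["burn_in"] * 3 + ["guided"] * 3
        assert len(res.observations) == 6

    def test_best_observed_is_running_minimum(self, small_cohort):
        res = self._loop(small_cohort, seed=1)
        ys = [o.y for o in res.observations]
        assert res.best_observed.y == min(ys)
        assert BOUNDS.contains(res.estimated_optimum)

    def test_identical_seed_reproduces_observation_sequence(self, small_cohort):
        a = self._loop(small_cohort, seed=2)
        b = self._loop(small_cohort, seed=2)
        for oa, ob in zip(a.observations, b.observations):
            assert oa.params == ob.params and oa.y == ob.y and oa.phase == ob.phase

    def test_per_second_acquisition_with_injected_time_model(self, small_cohort):
        res = self._loop(
            small_cohort, seed=3,
            spec=AcquisitionSpec("ei_per_second_plus"),
        )
        assert len(res.observations) == 6

    def test_fit_time_model_predicts_positive_seconds(self):
        observations = [obs(v, f, 0.3, t=0.5 + 0.1 * v) for v, f in
                        [(2, 2), (5, 5), (9, 7), (13, 3)]]
        tm = fit_time_model(observations, BOUNDS)
        assert np.all(tm(np.array([[3.0, 3.0], [12.0, 8.0]])) > 0)
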
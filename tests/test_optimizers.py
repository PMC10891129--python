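"""Unit tests for the from-scratch SGD / RMSprop / Adam fitters."""

import math

import numpy as np
import pytest

import optim_oracle
from conformnet import (
    DivergenceError,
    LinearModelParams,
    OptimizerConfig,
    fit_adam,
    fit_rmsprop,
    fit_sgd,
    generate_regression_data,
    least_squares_fit,
    objective_and_gradient,
    predict,
)

ONE_POINT = (np.array([1.0]), np.array([2.0]))


def cfg(method, **kw):
    kw.setdefault("init_seed", 5)
    kw.setdefault("shuffle_seed", 6)
    return OptimizerConfig(method=method, **kw)


class TestObjectiveAndGradient:
    def test_exact_fit_has_zero_objective_and_gradient(self):
        q, g = objective_and_gradient(
            LinearModelParams(0.0, 1.0), (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        )
        assert q == 0.0 and g == (0.0, 0.0)

    def test_hand_worked_value_at_origin(self):
        q, g = objective_and_gradient(
            LinearModelParams(0.0, 0.0), (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        )
        assert q == pytest.approx(0.5)
        assert g[0] == pytest.approx(-1.0) and g[1] == pytest.approx(-1.0)

    def test_intercept_gradient_vanishes_for_symmetric_data(self):
        x = np.array([0.2, 0.8, 0.5])
        y = np.array([1.5, 3.5, 2.0])  # symmetric about y = 2.3333... for theta=(c,0)
        c = y.mean()
        _, g = objective_and_gradient(LinearModelParams(c, 0.0), (x, y))
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            objective_and_gradient(LinearModelParams(0.0, 0.0), (np.array([]), np.array([])))


class TestPredict:
    def test_zero_parameters_give_zero(self):
        assert np.all(predict(LinearModelParams(0.0, 0.0), [0.3, 0.9]) == 0.0)

    def test_line_coefficients(self):
        assert predict(LinearModelParams(0.5, 0.79), 0.0) == pytest.approx(0.5)
        np.testing.assert_allclose(
            predict(LinearModelParams(1.0, 2.0), [0.0, 1.0, 2.0]), [1.0, 3.0, 5.0]
        )


class TestHandSteps:
    """Single-update values worked out by hand from the update rules."""

    def test_sgd_single_example_step(self):
        res = fit_sgd(ONE_POINT, cfg("SGD", eta=0.1, max_iters=1, grad_tol=0.0), theta_init=(0.0, 0.0))
        assert res.params.theta0 == pytest.approx(0.4, abs=1e-12)
        assert res.params.theta1 == pytest.approx(0.4, abs=1e-12)

    def test_rmsprop_first_batch_step(self):
        res = fit_rmsprop(ONE_POINT, cfg("RMSPROP", max_iters=1, grad_tol=0.0), theta_init=(0.0, 0.0))
        expected = 0.001 * 4.0 / math.sqrt(0.1 * 16.0 + 1e-6)
        assert res.params.theta0 == pytest.approx(expected, rel=1e-12)
        assert res.params.theta0 == pytest.approx(0.0031623, abs=1e-6)

    @pytest.mark.parametrize("mode", ["paper_literal", "time_scaled"])
    def test_adam_first_step_magnitude_is_learning_rate(self, mode):
        res = fit_adam(
            ONE_POINT,
            cfg("ADAM", max_iters=1, grad_tol=0.0, bias_correction=mode),
            theta_init=(0.0, 0.0),
        )
        # both bias-correction modes coincide at t=1 since 1-beta^1 = 1-beta
        assert res.params.theta0 == pytest.approx(0.001, abs=1e-6)
        assert res.params.theta1 == pytest.approx(0.001, abs=1e-6)


def _perm_table(shuffle_seed, epochs, m):
    rng = np.random.default_rng(shuffle_seed)
    return [list(rng.permutation(m)) for _ in range(epochs)]


class TestOracleEquivalence:
    """Five epochs on a fixed 8-point dataset must match the naive
    pure-Python transcription of the update rules per parameter."""

    EPOCHS = 5

    def test_sgd_matches_oracle(self, eight_point_dataset):
        x, y = eight_point_dataset
        c = cfg("SGD", max_iters=self.EPOCHS, grad_tol=0.0)
        res = fit_sgd((x, y), c, theta_init=(0.2, 0.7))
        t0, t1 = optim_oracle.sgd_epochs(
            x, y, 0.2, 0.7, c.eta, _perm_table(c.shuffle_seed, self.EPOCHS, len(x))
        )
        assert abs(res.params.theta0 - t0) <= 1e-10
        assert abs(res.params.theta1 - t1) <= 1e-10

    def test_rmsprop_matches_oracle(self, eight_point_dataset):
        x, y = eight_point_dataset
        c = cfg("RMSPROP", max_iters=self.EPOCHS, grad_tol=0.0, batch_size=4)
        res = fit_rmsprop((x, y), c, theta_init=(0.2, 0.7))
        t0, t1 = optim_oracle.rmsprop_epochs(
            x, y, 0.2, 0.7, c.eta, c.beta, c.eps, 4,
            _perm_table(c.shuffle_seed, self.EPOCHS, len(x)),
        )
        assert abs(res.params.theta0 - t0) <= 1e-10
        assert abs(res.params.theta1 - t1) <= 1e-10

    @pytest.mark.parametrize("mode", ["paper_literal", "time_scaled"])
    def test_adam_matches_oracle_in_both_bias_modes(self, eight_point_dataset, mode):
        x, y = eight_point_dataset
        c = cfg("ADAM", max_iters=self.EPOCHS, grad_tol=0.0, batch_size=4, bias_correction=mode)
        res = fit_adam((x, y), c, theta_init=(0.2, 0.7))
        t0, t1 = optim_oracle.adam_epochs(
            x, y, 0.2, 0.7, c.eta, c.beta1, c.beta2, c.adam_eps, 4,
            _perm_table(c.shuffle_seed, self.EPOCHS, len(x)), mode == "time_scaled",
        )
        assert abs(res.params.theta0 - t0) <= 1e-10
        assert abs(res.params.theta1 - t1) <= 1e-10


class TestConvergenceBehaviour:
    def test_all_fitters_recover_noiseless_line(self):
        ds = generate_regression_data("F1", m=100, seed=42, noise_sd=0.0)
        q_min, _ = objective_and_gradient(least_squares_fit(ds), ds)
        for fitter, method, tol in (
            (fit_sgd, "SGD", 0.02),
            (fit_rmsprop, "RMSPROP", 0.05),
            (fit_adam, "ADAM", 0.05),
        ):
            res = fitter(ds, cfg(method))
            assert abs(res.params.theta0 - 0.5) < tol, method
            assert abs(res.params.theta1 - 0.79) < tol, method
            q, _ = objective_and_gradient(res.params, ds)
            assert q - q_min < 1e-3

    def test_infinite_tolerance_stops_immediately(self):
        ds = generate_regression_data("F1", m=20, seed=0)
        res = fit_sgd(ds, cfg("SGD", grad_tol=np.inf))
        assert res.converged and res.epochs_run <= 1

    @pytest.mark.parametrize("fitter,method", [(fit_rmsprop, "RMSPROP"), (fit_adam, "ADAM")])
    def test_zero_gradient_is_fixed_point(self, fitter, method):
        x = np.linspace(0.1, 0.9, 12)
        y = 0.3 + 0.6 * x
        res = fitter((x, y), cfg(method, max_iters=5, grad_tol=-1.0), theta_init=(0.3, 0.6))
        assert res.params.theta0 == 0.3 and res.params.theta1 == 0.6

    def test_sgd_descent_is_monotone_on_noiseless_data(self):
        ds = generate_regression_data("F1", m=50, seed=9, noise_sd=0.0)
        res = fit_sgd(ds, cfg("SGD", max_iters=200, grad_tol=0.0))
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_divergence_raises_with_epoch(self):
        ds = generate_regression_data("F4", m=50, seed=3)
        with pytest.raises(DivergenceError) as err:
            fit_sgd(ds, cfg("SGD", eta=5.0, grad_tol=0.0))
        assert err.value.epoch >= 1

    def test_converged_flag_consistent_with_gradient_norm(self):
        ds = generate_regression_data("F3", m=50, seed=1)
        res = fit_sgd(ds, cfg("SGD", max_iters=3, grad_tol=1e-3))
        assert res.converged == (res.final_grad_norm <= 1e-3)
        assert not res.converged

    def test_fit_is_deterministic_under_seeds(self):
        ds = generate_regression_data("F1", m=30, seed=2)
        a = fit_adam(ds, cfg("ADAM", max_iters=50, grad_tol=0.0))
        b = fit_adam(ds, cfg("ADAM", max_iters=50, grad_tol=0.0))
        assert a.params == b.params
        np.testing.assert_array_equal(a.objective_trace, b.objective_trace)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw", [{"eta": 0.0}, {"beta": 1.0}, {"beta1": 0.0}, {"eps": 0.0}, {"batch_size": 0}]
    )
    def test_invalid_hyperparameters_rejected(self, kw):
        with pytest.raises(ValueError):
            OptimizerConfig(method="SGD", **kw)

    def test_method_mismatch_rejected(self):
        ds = generate_regression_data("F1", m=10, seed=0)
        with pytest.raises(ValueError):
            fit_sgd(ds, cfg("ADAM"))

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            LinearModelParams(np.nan, 0.0)


def test_least_squares_matches_polyfit():
    ds = generate_regression_data("F3", m=40, seed=8)
    ls = least_squares_fit(ds)
    slope, intercept = np.polyfit(ds.x, ds.y, 1)
    assert ls.theta0 == pytest.approx(intercept, rel=1e-9)
    assert ls.theta1 == pytest.approx(slope, rel=1e-9)

    res = fit_sgd(ds, cfg("SGD"))
    assert len(res.trace_frame()) == res.epochs_run + 1
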
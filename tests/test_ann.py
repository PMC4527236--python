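import math

import numpy as np
import pytest
from scipy.optimize import least_squares
from sklearn.base import clone

from mbcomtopt.ann import (
    ANNSurfaceRegressor,
    FitResult,
    NetworkParams,
    ScalingSpec,
    TrainingConfig,
    forward,
    jacobian,
    lm_sse_trace,
    load_fit,
    multistart_fit,
    n_parameters,
    save_fit,
    train_lm,
)
from mbcomtopt.dataset import inputs_matrix, observed_vector

BOX_LO = np.array([1.0, 20.0, 4.0])
BOX_HI = np.array([3.0, 30.0, 6.0])


def _random_params(rng, n_inputs=3, n_hidden=2, scale=0.8):
    return NetworkParams(
        hidden_weights=rng.uniform(-scale, scale, (n_hidden, n_inputs)),
        hidden_biases=rng.uniform(-scale, scale, n_hidden),
        output_weights=rng.uniform(-scale, scale, n_hidden),
        output_bias=rng.uniform(-scale, scale),
    )


def _natural_scaling():
    return ScalingSpec(BOX_LO, BOX_HI, 0.0, 400.0)


class TestParameterCount:
    @pytest.mark.parametrize(
        "i,h,o,expected", [(3, 2, 1, 11), (3, 3, 1, 16), (2, 2, 1, 9), (4, 5, 2, 37)]
    )
    def test_formula(self, i, h, o, expected):
        assert n_parameters(i, h, o) == expected

    def test_network_reports_its_free_parameters(self, rng):
        assert _random_params(rng).n_free == 11

    def test_vector_roundtrip(self, rng):
        params = _random_params(rng)
        back = NetworkParams.from_vector(params.to_vector(), 3, 2)
        assert np.array_equal(back.to_vector(), params.to_vector())


class TestForward:
    def test_zero_network_predicts_output_midpoint(self):
        params = NetworkParams(np.zeros((2, 3)), np.zeros(2), np.zeros(2), 0.0)
        sc = _natural_scaling()
        # scaled output 0 maps back to the midpoint of the response range
        assert forward(params, sc, np.array([2.0, 25.0, 5.0])) == 200.0
        assert forward(params, sc, np.array([1.0, 30.0, 6.0])) == 200.0

    def test_zero_hidden_weights_give_constant_surface(self, rng):
        params = NetworkParams(
            np.zeros((2, 3)), np.array([0.3, -0.7]), np.array([0.5, 0.2]), 0.1
        )
        sc = _natural_scaling()
        X = rng.uniform(BOX_LO, BOX_HI, (40, 3))
        preds = forward(params, sc, X)
        assert np.ptp(preds) == 0.0
        # input gradient vanishes everywhere: finite differences on forward
        x0 = np.array([2.0, 25.0, 5.0])
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = 1e-4
            assert forward(params, sc, x0 + dx) == forward(params, sc, x0 - dx)

    def test_matches_hand_composed_affine_tanh_evaluation(self):
        # independent scalar evaluation of scaling + tanh layer + unscaling
        params = NetworkParams(
            np.array([[0.5, -0.25, 0.1], [0.3, 0.2, -0.4]]),
            np.array([0.1, -0.2]),
            np.array([0.8, -0.5]),
            0.2,
        )
        sc = _natural_scaling()
        for x, expected in [
            ((2.0, 25.0, 5.0), 275.68441116248334),
            ((2.9, 30.0, 6.0), 313.7190923214418),
            ((1.0, 20.0, 4.0), 229.94427526056563),
        ]:
            xs = [2 * (xi - lo) / (hi - lo) - 1 for xi, lo, hi in zip(x, BOX_LO, BOX_HI)]
            h1 = math.tanh(0.5 * xs[0] - 0.25 * xs[1] + 0.1 * xs[2] + 0.1)
            h2 = math.tanh(0.3 * xs[0] + 0.2 * xs[1] - 0.4 * xs[2] - 0.2)
            by_hand = (0.8 * h1 - 0.5 * h2 + 0.2 + 1) / 2 * 400
            assert by_hand == pytest.approx(expected, abs=1e-12)
            assert forward(params, sc, np.array(x)) == pytest.approx(
                expected, abs=1e-9
            )

    def test_hidden_unit_permutation_symmetry(self, rng):
        params = _random_params(rng)
        swapped = NetworkParams(
            params.hidden_weights[::-1].copy(),
            params.hidden_biases[::-1].copy(),
            params.output_weights[::-1].copy(),
            params.output_bias,
        )
        sc = _natural_scaling()
        X = rng.uniform(BOX_LO, BOX_HI, (30, 3))
        assert np.allclose(forward(params, sc, X), forward(swapped, sc, X))

    def test_non_finite_input_raises(self, rng):
        params = _random_params(rng)
        with pytest.raises(ValueError, match="finite"):
            forward(params, _natural_scaling(), np.array([1.0, np.nan, 5.0]))


class TestJacobian:
    def test_agrees_with_central_finite_differences(self, rng):
        params = _random_params(rng)
        sc = _natural_scaling()
        X = rng.uniform(BOX_LO, BOX_HI, (12, 3))
        Xs = sc.scale_x(X)
        J = jacobian(params, sc, X)
        p = params.to_vector()
        step = 1e-6

        def f_scaled(pv):
            net = NetworkParams.from_vector(pv, 3, 2)
            H = np.tanh(Xs @ net.hidden_weights.T + net.hidden_biases)
            return H @ net.output_weights + net.output_bias

        for j in range(p.size):
            dp = np.zeros_like(p)
            dp[j] = step
            fd = (f_scaled(p + dp) - f_scaled(p - dp)) / (2 * step)
            denom = np.maximum(np.abs(fd), 1.0)
            assert np.max(np.abs(J[:, j] - fd) / denom) < 1e-5

    def test_output_layer_columns_have_closed_form(self, rng):
        params = _random_params(rng)
        sc = _natural_scaling()
        X = rng.uniform(BOX_LO, BOX_HI, (15, 3))
        J = jacobian(params, sc, X)
        H = np.tanh(sc.scale_x(X) @ params.hidden_weights.T + params.hidden_biases)
        assert np.allclose(J[:, 8:10], H)  # output-weight columns
        assert np.all(J[:, 10] == 1.0)  # output-bias column


class TestTrainLm:
    def test_recovers_linear_map_like_least_squares(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (20, 3))
        y = 2.0 + X @ np.array([0.3, -0.2, 0.1])
        fit = multistart_fit(X, y, TrainingConfig(n_restarts=50, seed=0))
        assert fit.sse <= 1e-8
        A = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.max(np.abs(fit.predict(X) - A @ coef)) < 1e-4

    def test_interpolates_when_parameters_match_data_count(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (11, 3))
        y = 100 + 50 * np.sin(X[:, 0]) + 3 * X[:, 1] - 4 * (X[:, 2] - 5) ** 2
        fit = multistart_fit(X, y, TrainingConfig(n_restarts=200, seed=0))
        assert fit.sse <= 1e-10

    def test_constant_response_is_fit_exactly(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (15, 3))
        fit = multistart_fit(
            X, np.full(15, 150.0), TrainingConfig(n_restarts=5, seed=0)
        )
        assert fit.sse <= 1e-10

    def test_final_sse_never_exceeds_initial(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (18, 3))
        y = rng.uniform(50, 350, 18)
        init = _random_params(rng)
        fit = train_lm(X, y, TrainingConfig(seed=0), init=init)
        scaling = fit.scaling
        r0 = scaling.scale_y(y) - (
            np.tanh(scaling.scale_x(X) @ init.hidden_weights.T + init.hidden_biases)
            @ init.output_weights
            + init.output_bias
        )
        assert fit.sse <= r0 @ r0 + 1e-15

    def test_accepted_sse_sequence_strictly_decreases(self, calibration_records):
        X = inputs_matrix(calibration_records)
        y = observed_vector(calibration_records)
        trace = lm_sse_trace(X, y, TrainingConfig(seed=0))
        assert len(trace) > 2
        assert np.all(np.diff(trace) < 0)

    def test_converged_fit_has_small_gradient(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (20, 3))
        y = 2.0 + X @ np.array([0.3, -0.2, 0.1])
        cfg = TrainingConfig(n_restarts=30, seed=0)
        fit = multistart_fit(X, y, cfg)
        if fit.converged:
            r = fit.scaling.scale_y(y) - fit.scaling.scale_y(fit.predict(X))
            g = jacobian(fit.params, fit.scaling, X).T @ r
            assert np.linalg.norm(g) < cfg.gradient_tolerance

    def test_matches_independent_nonlinear_least_squares(
        self, calibration_records, final_fit
    ):
        """scipy's trust-region LM run from 20 seeded starts reaches the same
        minimum SSE as the in-package trainer."""
        X = inputs_matrix(calibration_records)
        y = observed_vector(calibration_records)
        sc = final_fit.scaling
        Xs, ys = sc.scale_x(X), sc.scale_y(y)

        def resid(p):
            net = NetworkParams.from_vector(p, 3, 2)
            H = np.tanh(Xs @ net.hidden_weights.T + net.hidden_biases)
            return ys - (H @ net.output_weights + net.output_bias)

        rng = np.random.default_rng(0)
        scipy_best = min(
            2 * least_squares(resid, rng.uniform(-0.5, 0.5, 11), method="lm").cost
            for _ in range(20)
        )
        assert final_fit.sse == pytest.approx(scipy_best, abs=1e-6)

    def test_single_restart_equals_train_lm_with_same_seed(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (15, 3))
        y = rng.uniform(50, 350, 15)
        cfg = TrainingConfig(n_restarts=1, seed=42)
        a = multistart_fit(X, y, cfg)
        b = train_lm(X, y, cfg)
        assert np.array_equal(a.params.to_vector(), b.params.to_vector())
        assert a.sse == b.sse

    def test_best_sse_non_increasing_in_restart_count(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (15, 3))
        y = rng.uniform(50, 350, 15)
        sses = [
            multistart_fit(X, y, TrainingConfig(n_restarts=n, seed=7)).sse
            for n in (1, 3, 10, 25)
        ]
        assert all(b <= a + 1e-18 for a, b in zip(sses, sses[1:]))

    def test_rejects_non_finite_training_data(self):
        with pytest.raises(ValueError, match="finite"):
            train_lm(np.array([[1.0, 2.0, np.inf]]), np.array([1.0]))


class TestScalingSpec:
    def test_degenerate_ranges_are_padded(self):
        sc = ScalingSpec.from_data(
            np.array([[2.0, 25.0, 5.0], [2.0, 30.0, 5.0]]), np.array([100.0, 100.0])
        )
        assert np.all(sc.x_max > sc.x_min)
        assert sc.y_max > sc.y_min
        assert np.allclose(sc.scale_x([[2.0, 25.0, 5.0]])[0, [0, 2]], 0.0)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError, match="max > min"):
            ScalingSpec(np.array([1.0]), np.array([1.0]), 0.0, 1.0)


class TestTrainingConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_epochs": 0},
            {"rate_increase_ratio": 1.0},
            {"sse_tolerance": 0.0},
            {"n_restarts": 0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)


class TestEstimator:
    def test_fit_predict_and_fitted_attributes(self, calibration_records):
        X = inputs_matrix(calibration_records)
        y = observed_vector(calibration_records)
        est = ANNSurfaceRegressor(n_restarts=5, random_state=3)
        est.fit(X, y)
        assert est.network_.n_free == 11
        assert est.sse_ >= 0
        assert est.predict(X).shape == (25,)

    def test_clone_reproduces_fit(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (15, 3))
        y = rng.uniform(50, 350, 15)
        est = ANNSurfaceRegressor(n_restarts=4, random_state=11)
        a = est.fit(X, y).predict(X)
        b = clone(est).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_estimator_agrees_with_functional_api(self, rng):
        X = rng.uniform(BOX_LO, BOX_HI, (15, 3))
        y = rng.uniform(50, 350, 15)
        est = ANNSurfaceRegressor(n_restarts=6, random_state=5).fit(X, y)
        fn = multistart_fit(X, y, TrainingConfig(n_restarts=6, seed=5))
        assert np.array_equal(
            est.network_.to_vector(), fn.params.to_vector()
        )
        assert np.array_equal(est.predict(X), np.asarray(fn.predict(X)))


class TestSerialization:
    def test_yaml_roundtrip_reproduces_predictions_bit_exactly(
        self, final_fit, tmp_path, rng
    ):
        path = tmp_path / "model.yaml"
        save_fit(final_fit, path)
        back = load_fit(path)
        X = rng.uniform(BOX_LO, BOX_HI, (50, 3))
        assert np.array_equal(
            np.asarray(final_fit.predict(X)), np.asarray(back.predict(X))
        )
        assert back.sse == final_fit.sse
        assert back.config == final_fit.config

    def test_negative_sse_rejected(self, final_fit):
        with pytest.raises(ValueError, match="sse"):
            FitResult(
                params=final_fit.params,
                scaling=final_fit.scaling,
                sse=-1.0,
                epochs_run=1,
                converged=False,
            )
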
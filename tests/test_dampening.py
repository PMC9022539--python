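"""Response-curve fitting, layer propagation, and parameter recovery."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coordbio.dampening import (
    DampeningParams,
    LayerNetwork,
    fit_response_curve,
    predict_target_level,
    propagate_layers,
    recover_params,
    simulate_series,
)
from coordbio.synthetic import generate_concentration_series


def three_layer_network(coupling=(0.6, 0.4)):
    return LayerNetwork(layers=[["m0"], ["m1"], ["m2"]], coupling=list(coupling))


class TestFitResponseCurve:
    def test_exact_linear_recovery(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [2 * v + 1 for v in x]
        curve = fit_response_curve(x, y, degree=1)
        assert curve.coefficients == pytest.approx((1.0, 2.0), abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_quadratic_recovery_from_noiseless_points(self):
        x = np.linspace(0, 5, 6)
        y = 1 + 0.5 * x + 0.25 * x**2
        curve = fit_response_curve(x, y, degree=2)
        assert curve.coefficients == pytest.approx((1.0, 0.5, 0.25), abs=1e-9)
        assert curve(2.0) == pytest.approx(1 + 1 + 1, abs=1e-9)

    def test_constant_series_zero_high_order(self):
        curve = fit_response_curve([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0], degree=2)
        assert curve.coefficients[0] == pytest.approx(5.0, abs=1e-9)
        assert curve.coefficients[1] == pytest.approx(0.0, abs=1e-9)
        assert curve.coefficients[2] == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == 1.0  # zero variance explained exactly

    def test_insufficient_points_named_error(self):
        with pytest.raises(ValueError, match="distinct primary levels"):
            fit_response_curve([1.0, 1.0, 1.0], [1, 2, 3], degree=2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            fit_response_curve([1, 2, 3], [1, 2], degree=1)


class TestPropagateLayers:
    def test_decoupled_layers_are_zero(self):
        levels = propagate_layers(three_layer_network((0.0, 0.0)), 10.0)
        assert levels == {0: 10.0, 1: 0.0, 2: 0.0}

    def test_geometric_recursion(self):
        net = LayerNetwork(layers=[["a"], ["b"], ["c"], ["d"]], coupling=[0.5, 0.5, 0.5])
        assert propagate_layers(net, 8.0) == {0: 8.0, 1: 4.0, 2: 2.0, 3: 1.0}

    def test_full_coupling_conserves_level(self):
        levels = propagate_layers(three_layer_network((1.0, 1.0)), 3.5)
        assert set(levels.values()) == {3.5}

    def test_non_increasing_when_coupling_below_one(self):
        levels = propagate_layers(three_layer_network((0.9, 0.7)), 5.0)
        vals = [levels[i] for i in sorted(levels)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_coupling_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            LayerNetwork(layers=[["a"], ["b"]], coupling=[1.5])


class TestPredictTargetLevel:
    PARAMS = DampeningParams(w=0.5, beta=1.0, baseline=2.0)

    def test_zero_mirna_levels_give_baseline(self):
        assert predict_target_level({0: 0.0, 1: 0.0}, 1, self.PARAMS) == 2.0

    def test_single_layer_closed_form(self):
        # beta=1, level=ln 2 at distance 0 -> baseline / 2
        params = DampeningParams(w=0.3, beta=1.0, baseline=1.0)
        assert predict_target_level({0: math.log(2)}, 0, params) == pytest.approx(0.5)

    def test_distance_one_attenuates_by_w(self):
        params = DampeningParams(w=0.5, beta=1.0, baseline=1.0)
        level = 0.7
        near = -math.log(predict_target_level({1: level}, 1, params))
        far = -math.log(predict_target_level({0: level, 1: 0.0}, 1, params))
        assert near == pytest.approx(2 * far)

    def test_bounded_in_zero_baseline(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            levels = {i: float(rng.uniform(0, 5)) for i in range(3)}
            val = predict_target_level(levels, 2, self.PARAMS)
            assert 0.0 < val <= self.PARAMS.baseline

    def test_monotone_in_any_mirna_level(self):
        base = {0: 1.0, 1: 0.5, 2: 0.25}
        ref = predict_target_level(base, 2, self.PARAMS)
        for layer in base:
            bumped = dict(base)
            bumped[layer] += 0.1
            assert predict_target_level(bumped, 2, self.PARAMS) < ref

    def test_downstream_layers_do_not_repress_upstream_targets(self):
        only_deep = {0: 0.0, 1: 0.0, 2: 3.0}
        assert predict_target_level(only_deep, 0, self.PARAMS) == self.PARAMS.baseline

    def test_invalid_params_rejected(self):
        for kwargs in (dict(w=0.0), dict(w=1.0), dict(beta=-1.0), dict(baseline=0.0)):
            with pytest.raises(ValueError):
                DampeningParams(**kwargs)


class TestRecoverParams:
    DOSES = [0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0]

    def test_noiseless_recovery_to_1e6(self):
        truth = DampeningParams(w=0.5, beta=1.0, baseline=1.0)
        series = generate_concentration_series(truth, three_layer_network(), self.DOSES)
        curve, est = recover_params(series)
        assert est.w == pytest.approx(truth.w, abs=1e-6)
        assert est.beta == pytest.approx(truth.beta, abs=1e-6)
        assert est.baseline == pytest.approx(truth.baseline, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0)

    def test_response_curve_matches_coupling(self):
        # layer-1 level is linear in layer-0 level with slope c_1
        truth = DampeningParams(w=0.4, beta=0.8, baseline=1.0)
        series = generate_concentration_series(truth, three_layer_network((0.6, 0.4)), self.DOSES)
        curve, _ = recover_params(series, degree=1)
        assert curve.coefficients == pytest.approx((0.0, 0.6), abs=1e-9)

    def test_single_layer_not_identifiable(self):
        truth = DampeningParams(w=0.5, beta=1.0, baseline=1.0)
        net = LayerNetwork(layers=[["only"]], coupling=[])
        series = simulate_series(truth, net, self.DOSES)
        with pytest.raises(ValueError, match="identifiable"):
            recover_params(series)

    def test_noise_degrades_recovery_on_average(self):
        """Mean |w_hat - w| over seeds grows from sigma=0 to sigma=0.05."""
        truth = DampeningParams(w=0.5, beta=1.0, baseline=1.0)
        net = three_layer_network()
        errors = {}
        for sigma in (0.0, 0.05):
            errs = []
            for seed in range(30):
                series = generate_concentration_series(
                    truth, net, self.DOSES, noise_sigma=sigma, seed=seed
                )
                _, est = recover_params(series)
                errs.append(abs(est.w - truth.w))
            errors[sigma] = float(np.mean(errs))
        assert errors[0.05] > errors[0.0]


class TestSimulateSeries:
    def test_doubling_beta_lowers_every_positive_dose_target(self):
        net = three_layer_network()
        weak = simulate_series(DampeningParams(w=0.5, beta=1.0), net, [0.5, 1.0, 2.0])
        strong = simulate_series(DampeningParams(w=0.5, beta=2.0), net, [0.5, 1.0, 2.0])
        assert (strong["target_level"] < weak["target_level"]).all()

    def test_fixed_seed_reproducible(self):
        truth = DampeningParams(w=0.5, beta=1.0)
        net = three_layer_network()
        a = generate_concentration_series(truth, net, [0.5, 1.0], noise_sigma=0.1, seed=11)
        b = generate_concentration_series(truth, net, [0.5, 1.0], noise_sigma=0.1, seed=11)
        assert a.equals(b)

    def test_zero_noise_equals_forward_model(self):
        truth = DampeningParams(w=0.5, beta=1.0)
        net = three_layer_network()
        assert generate_concentration_series(truth, net, [1.0, 2.0], noise_sigma=0.0).equals(
            simulate_series(truth, net, [1.0, 2.0])
        )
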
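"""Objectives, network algebra, collocation transcription and multistart."""

import numpy as np
import pytest

from hybridkin.data import SpikeSchedule
from hybridkin.dynopt.ann import ANNSpec
from hybridkin.dynopt.collocation import (
    CollocationGrid,
    CollocationProblem,
    ParamMap,
    collocation_simulate,
    complex_step_jacobian,
    radau_points,
)
from hybridkin.dynopt.objectives import mse_objective, smoothness_penalty
from hybridkin.dynopt.solve import MultistartConfig, solve_multistart
from hybridkin.ground_truth import gt_rhs
from hybridkin.hybrid import hybrid_rhs, improved_rhs
from hybridkin.phenom import phenom_rhs, phenom_problem


class TestObjectives:
    def test_mse_trivial_cases(self):
        a = np.zeros((2, 3, 4))
        assert mse_objective(a, a) == 0.0
        assert mse_objective(np.full((1, 1, 1), 3.0), np.full((1, 1, 1), 1.0)) == 4.0

    def test_mse_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(3, 5, 4))
        act = rng.normal(size=(3, 5, 4))
        scale = rng.uniform(0.5, 2.0, 4)
        total = 0.0
        for i in range(3):
            for j in range(5):
                for s in range(4):
                    total += ((pred[i, j, s] - act[i, j, s]) / scale[s]) ** 2
        expected = total / (3 * 5 * 4)
        assert np.isclose(mse_objective(pred, act, scale), expected, rtol=1e-13)

    def test_smoothness_vanishes_for_constant_and_linear(self):
        const = np.full((2, 6), 1.3)
        linear = np.tile(np.arange(6.0) * 0.7 - 1.0, (2, 1))
        assert smoothness_penalty(const) == 0.0
        assert smoothness_penalty(linear) == pytest.approx(0.0, abs=1e-25)

    def test_smoothness_closed_form_quadratic(self):
        # second differences of [0,1,4,9,16] are all 2 -> (3*4)/(1*5)
        theta = np.array([[0.0, 1.0, 4.0, 9.0, 16.0]])
        assert smoothness_penalty(theta) == pytest.approx(2.4, rel=1e-14)

    def test_smoothness_needs_three_points(self):
        with pytest.raises(ValueError):
            smoothness_penalty(np.ones((1, 2)))


class TestANN:
    def test_zero_network_outputs_zero(self):
        spec = ANNSpec(n_inputs=3, hidden=(4,))
        assert np.allclose(spec.forward(np.array([1.0, -2.0, 3.0])), 0.0)

    def test_single_linear_layer_is_affine(self):
        spec = ANNSpec(n_inputs=2, hidden=(), output_activation="identity")
        spec.weights = [np.array([[2.0], [-1.0]])]
        spec.biases = [np.array([0.5])]
        x = np.array([3.0, 4.0])
        assert np.isclose(spec.forward(x)[0], 2 * 3 - 4 + 0.5)

    def test_matches_independent_tensor_implementation(self):
        rng = np.random.default_rng(2)
        spec = ANNSpec(n_inputs=4, hidden=(5, 3), output_activation="sigmoid")
        spec.set_flat(rng.uniform(-1, 1, spec.n_params))
        spec.with_input_scaling(np.array([0, 0, 0, 0.0]), np.array([1, 2, 3, 4.0]))
        x = rng.uniform(0, 2, (7, 4))
        # independent loop-based forward pass
        for row in range(7):
            h = (x[row] - spec.input_offset) * spec.input_scale
            for li, (W, b) in enumerate(zip(spec.weights, spec.biases)):
                z = np.array([sum(h[i] * W[i, o] for i in range(W.shape[0])) + b[o]
                              for o in range(W.shape[1])])
                h = np.tanh(z) if li < 2 else 1 / (1 + np.exp(-z))
            assert np.allclose(spec.forward(x)[row], h, atol=1e-12)

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        spec = ANNSpec(n_inputs=3, hidden=(6,), output_activation="identity")
        spec.set_flat(rng.uniform(-1, 1, spec.n_params))
        x = rng.uniform(-1, 1, 3)
        grad = spec.input_gradient(x)[0]
        for i in range(3):
            dx = np.zeros(3)
            dx[i] = 1e-7
            fd = (spec.forward(x + dx)[0] - spec.forward(x - dx)[0]) / 2e-7
            assert np.isclose(grad[i], fd, rtol=1e-5, atol=1e-9)

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(4)
        spec = ANNSpec(n_inputs=4, hidden=(4,), bounded=True,
                       input_names=("a", "b", "c", "d"))
        spec.set_flat(rng.uniform(-1, 1, spec.n_params))
        back = ANNSpec.from_dict(spec.to_dict())
        x = rng.uniform(0, 1, (5, 4))
        assert np.allclose(back.forward(x), spec.forward(x), atol=1e-15)

    def test_nlp_expression_path_equals_numeric_path(self):
        """Embedded (flat-weight) evaluation must agree with the standalone
        forward pass to near machine precision."""
        rng = np.random.default_rng(5)
        spec = ANNSpec(n_inputs=4, hidden=(4,))
        flat = rng.uniform(-1, 1, spec.n_params)
        spec.set_flat(flat)
        x = rng.uniform(0, 1, (6, 4))
        via_flat = ANNSpec.forward_flat(spec, flat, x)
        assert np.max(np.abs(via_flat - spec.forward(x))) < 1e-10


class TestCollocation:
    def test_radau_points_known_values(self):
        c3 = radau_points(3)
        assert np.allclose(c3, [(4 - np.sqrt(6)) / 10, (4 + np.sqrt(6)) / 10, 1.0])
        assert radau_points(1) == (1.0,)

    def test_complex_step_matches_analytic_derivative(self):
        f = lambda x: np.stack([np.sin(x[..., 0]) * x[..., 1],
                                x[..., 0] ** 3], axis=-1)
        x = np.array([0.7, 1.3])
        J = complex_step_jacobian(f, x)
        expected = np.array([[np.cos(0.7) * 1.3, np.sin(0.7)],
                             [3 * 0.7 ** 2, 0.0]])
        assert np.allclose(J, expected, rtol=1e-13)

    @pytest.mark.parametrize("family", ["ground_truth", "phenom", "hybrid",
                                        "improved"])
    def test_transcription_fidelity(self, family, gt_params, clean_data,
                                    batch_trajectories):
        """Collocation states match the adaptive integrator within 1e-4
        relative at every measurement node, for each model family."""
        from scipy.integrate import solve_ivp

        times = clean_data.times
        grid = CollocationGrid(tuple(times), K=5, nsub=2)  # the default fit grid
        theta = {"Y_xg": 0.04, "Y_mx": 2.0, "beta": 0.35, "k_cr": 5.0,
                 "mu_g": 0.25, "K_g": 5.0, "k_g": 5.0, "mu_c": 0.04,
                 "K_c": 15.0}
        theta_b = {k: np.asarray(v) for k, v in theta.items()}

        if family == "ground_truth":
            y0 = batch_trajectories[0].metadata["init"]
            rhs = lambda y, th, mu: gt_rhs(y, gt_params, y0[2])
            ode = lambda t, y: gt_rhs(np.asarray(y), gt_params, y0[2])
            march = collocation_simulate(grid, rhs, np.asarray(y0))
        else:
            y0 = np.array([0.01, 60.0, 30.0, 0.0])
            if family == "phenom":
                rhs = phenom_rhs
                ode = lambda t, y: phenom_rhs(np.asarray(y), theta_b)
                march = collocation_simulate(grid, rhs, y0, theta=theta_b)
            else:
                # time-variant modulation fixed at the measurement nodes and
                # linearly interpolated — the transcription's definition —
                # with the reference ODE using the identical interpolant
                if family == "hybrid":
                    rhs = hybrid_rhs
                    nodes = np.array([0.23, 0.21, 0.18, 0.12, 0.05, 0.01,
                                      0.0, 0.0, 0.0, 0.0])
                else:
                    rhs = improved_rhs
                    nodes = np.array([0.95, 0.9, 0.85, 0.75, 0.65, 0.6,
                                      0.55, 0.5, 0.45, 0.4])
                mu_of_t = lambda t: np.interp(t, times, nodes)
                ode = lambda t, y: rhs(np.asarray(y), theta_b, mu_of_t(t))
                march = collocation_simulate(grid, rhs, y0, theta=theta_b,
                                             mu_nodes=nodes)
        ref = solve_ivp(ode, (0.0, 72.0), np.asarray(y0, float), method="LSODA",
                        t_eval=times, rtol=1e-10, atol=1e-12).y.T
        scale = np.abs(ref).max(axis=0)
        assert np.max(np.abs(march - ref) / scale) < 1e-4

    def test_collocation_constraints_hold_at_reduced_solution(
        self, phenom_clean_data, phenom_truth
    ):
        from hybridkin.phenom import PHENOM_PARAM_NAMES

        problem, _ = phenom_problem(phenom_clean_data)
        p = np.array([phenom_truth.as_dict()[n] for n in PHENOM_PARAM_NAMES])
        res = problem.constraint_residuals(p)
        assert np.max(np.abs(res)) < 1e-8

    def test_objective_decomposes_into_mse_plus_smoothing(self, clean_data):
        from hybridkin.hybrid import HYBRID_TIV, estimate_growth_nodes

        pmap = ParamMap(tiv_names=HYBRID_TIV, n_times=clean_data.n_times,
                        n_tv_conditions=clean_data.n_conditions)
        problem = CollocationProblem(hybrid_rhs, clean_data, pmap,
                                     w_m=1.0, w_s=7.0)
        mu = estimate_growth_nodes(clean_data)
        p = np.concatenate([[0.04, 2.0, 0.35, 5.0], mu.ravel()])
        r = problem.residuals(p)
        parts = problem.objective_parts(p)
        assert np.isclose(float(r @ r),
                          1.0 * parts["mse"] + 7.0 * parts["smoothing"],
                          rtol=1e-12)

    def test_measurement_grid_mismatch_rejected(self, clean_data):
        from hybridkin.hybrid import HYBRID_TIV

        pmap = ParamMap(tiv_names=HYBRID_TIV, n_times=7, n_tv_conditions=3)
        with pytest.raises(ValueError, match="grid"):
            CollocationProblem(hybrid_rhs, clean_data, pmap)


class TestMultistart:
    def _small_problem(self, data):
        return phenom_problem(data)

    def test_deterministic_under_seed(self, phenom_clean_data):
        problem, sampler = self._small_problem(phenom_clean_data)
        cfg = MultistartConfig(n_starts=2, seed=9, max_nfev=40)
        a = solve_multistart(problem, sampler, cfg)
        problem2, sampler2 = self._small_problem(phenom_clean_data)
        b = solve_multistart(problem2, sampler2, cfg)
        assert a.objective == b.objective
        assert np.array_equal(a.p, b.p)

    def test_best_not_worse_than_any_start_and_monotone(self, phenom_clean_data):
        problem, sampler = self._small_problem(phenom_clean_data)
        res4 = solve_multistart(problem, sampler,
                                MultistartConfig(n_starts=4, seed=1, max_nfev=30))
        objs = [e["objective"] for e in res4.start_log if e.get("usable")]
        assert res4.objective <= min(objs) + 1e-15
        # same seed sequence, fewer starts: prefix property => monotone best
        problem2, sampler2 = self._small_problem(phenom_clean_data)
        res2 = solve_multistart(problem2, sampler2,
                                MultistartConfig(n_starts=2, seed=1, max_nfev=30))
        assert res4.objective <= res2.objective + 1e-15
        assert [e["start"] for e in res4.start_log] == [0, 1, 2, 3]
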
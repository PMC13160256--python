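"""Hybrid model structure, TVPE behaviour, network regression, simulation."""

import warnings

import numpy as np
import pytest

from hybridkin.data import SpikeSchedule
from hybridkin.dynopt.ann import ANNSpec
from hybridkin.dynopt.solve import MultistartConfig
from hybridkin.hybrid import (
    estimate_growth_nodes,
    rhs_hybrid,
    rhs_improved,
    simulate_hybrid,
    train_tv_ann,
    tvpe_sequential,
)
from hybridkin.phenom import rhs_phenom, PhenomParams
from hybridkin.results import FitResult

TIV = {"Y_xg": 0.04, "Y_mx": 2.0, "beta": 0.35, "k_cr": 5.0}
TIV_IMPROVED = {"mu_g": 0.25, "k_g": 5.0, **TIV}


class TestRHS:
    def test_dormant_culture_is_static_in_batch(self):
        d = rhs_hybrid(np.array([1.0, 30.0, 10.0, 5.0]),
                       {**TIV, "beta": 0.0}, 0.0)
        assert np.allclose(d, 0.0)

    def test_no_catechol_stops_product_formation(self):
        d = rhs_hybrid(np.array([1.0, 30.0, 0.0, 5.0]), TIV, 0.1)
        assert d[2] == 0.0 and d[3] == 0.0

    def test_matches_independent_scalar_evaluation(self):
        Xt, Cg, Cc, Cm, mu = 1.3, 20.0, 8.0, 12.0, 0.07
        prod = (TIV["Y_mx"] * mu + TIV["beta"]) * Xt * Cc / (Cc + TIV["k_cr"])
        expected = [mu * Xt, -mu / TIV["Y_xg"] * Xt, -prod, prod]
        assert np.allclose(rhs_hybrid(np.array([Xt, Cg, Cc, Cm]), TIV, mu),
                           expected, rtol=1e-13)

    def test_improved_with_full_viability_reduces_to_monod_model(self):
        """f_v = 1 must coincide term-by-term with the phenomenological
        structure at zero catechol toxicity (mu_c = 0)."""
        state = np.array([0.8, 25.0, 14.0, 6.0])
        got = rhs_improved(state, TIV_IMPROVED, 1.0)
        params = PhenomParams(mu_g=0.25, K_g=5.0, mu_c=0.0, K_c=1.0,
                              Y_xg=0.04, Y_mx=2.0, beta=0.35, k_cr=5.0)
        assert np.allclose(got, rhs_phenom(state, params), rtol=1e-13)

    def test_improved_with_zero_viability_is_static(self):
        d = rhs_improved(np.array([2.0, 25.0, 14.0, 6.0]), TIV_IMPROVED, 0.0)
        assert np.allclose(d, 0.0)

    def test_improved_matches_scalar_evaluation(self):
        Xt, Cg, Cc, Cm, fv = 1.1, 18.0, 9.0, 3.0, 0.6
        mu = 0.25 * Cg / (Cg + 5.0)
        prod = (2.0 * mu + 0.35) * fv * Xt * Cc / (Cc + 5.0)
        expected = [mu * fv * Xt, -mu / 0.04 * fv * Xt, -prod, prod]
        got = rhs_improved(np.array([Xt, Cg, Cc, Cm]), TIV_IMPROVED, fv)
        assert np.allclose(got, expected, rtol=1e-13)

    def test_viable_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="viable fraction"):
            rhs_improved(np.array([1.0, 1.0, 1.0, 1.0]), TIV_IMPROVED, 1.2)


class TestTVPE:
    def test_huge_smoothing_forces_zero_curvature(self, clean_data):
        """As w_s -> inf the recovered trajectories lose all curvature
        (second differences vanish; the penalty-free limit is linear in
        the node index)."""
        weak = tvpe_sequential(clean_data, w_s=0.1,
                               config=MultistartConfig(n_starts=1, seed=0,
                                                       max_nfev=60))
        strong = tvpe_sequential(clean_data, w_s=1e6,
                                 config=MultistartConfig(n_starts=1, seed=0,
                                                         max_nfev=60))
        def curvature(tvp):
            return np.max(np.abs(np.diff(tvp, n=2, axis=1)))

        spread = np.ptp(weak.tvp)
        assert curvature(strong.tvp) < 1e-3 * spread
        assert curvature(strong.tvp) < 1e-2 * curvature(weak.tvp)

    def test_recovers_effective_growth_rate(self, clean_data, oracle_growth):
        """On noise-free data with little smoothing, the recovered rate
        tracks the dense-truth effective growth rate (dXt/dt)/Xt at every
        interior node where the rate is appreciable."""
        out = tvpe_sequential(clean_data, w_s=0.1,
                              config=MultistartConfig(n_starts=2, seed=0,
                                                      max_nfev=120))
        interior = slice(1, -1)
        mu_hat = out.tvp[:, interior]
        mu_true = oracle_growth[:, interior]
        mask = np.abs(mu_true) >= 0.05 * np.abs(oracle_growth).max()
        rel = np.abs(mu_hat[mask] - mu_true[mask]) / np.abs(mu_true[mask])
        assert np.max(rel) < 0.10
        assert all(v >= 0 for v in out.tiv.values())

    def test_negative_weights_rejected(self, clean_data):
        with pytest.raises(ValueError):
            tvpe_sequential(clean_data, w_m=-1.0)


class TestTrainTVANN:
    def _fake_tvpe(self, data, tvp):
        return FitResult(model="tvpe", tiv={}, objective=0.0, tvp=tvp,
                         tvp_times=np.array(data.times))

    def test_constant_target_learned_exactly(self, clean_data):
        tvp = np.full((3, 10), 0.07)
        ann, record = train_tv_ann(
            self._fake_tvpe(clean_data, tvp), clean_data,
            arch_grid=[{"hidden": (4,), "alpha": 0.0}], seed=0,
        )
        X = clean_data.observations.reshape(-1, 4)
        pred = ann.forward(X)[:, 0]
        assert np.max(np.abs(pred - 0.07)) < 0.01 * 0.07

    def test_cv_record_bookkeeping(self, clean_data):
        tvp = np.full((3, 10), 0.05)
        grid = [{"hidden": (4,), "alpha": 0.0}, {"hidden": (8,), "alpha": 1e-4}]
        _, record = train_tv_ann(self._fake_tvpe(clean_data, tvp), clean_data,
                                 arch_grid=grid, k_folds=5, seed=0)
        assert len(record) == 5 * len(grid)
        assert all("val_mse" in e for e in record)

    def test_smooth_function_of_state_learned_well(self, clean_data,
                                                   batch_trajectories):
        """R^2 > 0.95 on unseen states when the target is a smooth known
        function of the measured state."""
        def f(obs):
            return (0.2 * obs[..., 1] / (obs[..., 1] + 10.0)
                    - 0.04 * obs[..., 2] / (obs[..., 2] + 20.0))

        target = f(clean_data.observations)
        ann, _ = train_tv_ann(
            self._fake_tvpe(clean_data, target), clean_data,
            arch_grid=[{"hidden": (8,), "alpha": 1e-5}], seed=0,
        )
        # held-out states: the same cultures observed at off-grid times
        t_held = np.linspace(4.0, 68.0, 15)
        X_held = np.vstack([tr.at(t_held, ("Xt", "Cg", "Cc", "Cm"))
                            for tr in batch_trajectories])
        y_held = f(X_held)
        pred = ann.forward(X_held)[:, 0]
        ss_res = np.sum((pred - y_held) ** 2)
        ss_tot = np.sum((y_held - y_held.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95

    def test_grid_mismatch_rejected(self, clean_data):
        bad = FitResult(model="tvpe", tiv={}, objective=0.0,
                        tvp=np.zeros((3, 7)), tvp_times=np.arange(7.0))
        with pytest.raises(ValueError):
            train_tv_ann(bad, clean_data)


class TestSimulateHybrid:
    def _zero_net_fit(self):
        ann = ANNSpec(n_inputs=4, hidden=(4,), output_activation="identity",
                      input_names=("Xt", "Cg", "Cc", "Cm"))
        ann.with_input_scaling(np.zeros(4), np.array([2.5, 70.0, 35.0, 30.0]))
        return FitResult(model="hybrid_integrated",
                         tiv={**TIV, "beta": 0.0}, objective=0.0, ann=ann)

    def test_zero_network_and_zero_beta_is_static_in_batch(self):
        fit = self._zero_net_fit()
        tr = simulate_hybrid(fit, np.array([0.5, 60.0, 30.0, 0.0]),
                             SpikeSchedule.batch(72.0))
        assert np.allclose(tr.states, tr.states[0], atol=1e-9)

    def test_batch_conservation(self, clean_data):
        rng = np.random.default_rng(0)
        ann = ANNSpec(n_inputs=4, hidden=(4,), input_names=("Xt", "Cg", "Cc", "Cm"))
        flat = rng.uniform(-0.3, 0.3, ann.n_params)
        flat[-1] = 0.1
        ann.set_flat(flat)
        ann.with_input_scaling(np.zeros(4), np.array([2.5, 70.0, 35.0, 30.0]))
        fit = FitResult(model="hybrid_integrated", tiv=TIV, objective=0.0, ann=ann)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = simulate_hybrid(fit, np.array([0.01, 60.0, 30.0, 0.0]),
                                 SpikeSchedule.batch(72.0))
        assert np.max(np.abs(tr["Cc"] + tr["Cm"] - 30.0)) < 1e-6

    def test_missing_network_rejected(self):
        fit = FitResult(model="hybrid_sequential", tiv=TIV, objective=0.0)
        with pytest.raises(ValueError, match="network"):
            simulate_hybrid(fit, np.zeros(4), SpikeSchedule.batch(72.0))

    def test_growth_estimate_shape(self, clean_data):
        mu = estimate_growth_nodes(clean_data)
        assert mu.shape == (clean_data.n_conditions, clean_data.n_times)
        assert np.all(np.isfinite(mu))
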
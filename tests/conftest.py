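"""Shared fixtures.

Expensive artifacts (ground-truth trajectories, fitted models, full study
runs) are session-scoped so the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridkin.config import smoke_config
from hybridkin.data import MeasurementDataset, NoiseSpec, SpikeSchedule
from hybridkin.ground_truth import (
    GroundTruthState,
    default_params,
    generate_dataset,
    sample_initial_conditions,
    simulate,
)
from hybridkin.phenom import PhenomParams, simulate_phenom

#: the three seeds of the study-level (stochastic) acceptance checks
STUDY_SEEDS = (101, 202, 303)


@pytest.fixture(scope="session")
def gt_params():
    return default_params()


@pytest.fixture(scope="session")
def batch_trajectories(gt_params):
    """Dense 72 h batch trajectories from the default training design."""
    inits = sample_initial_conditions(3, seed=42)
    return [simulate(gt_params, ic, SpikeSchedule.batch(72.0)) for ic in inits]


@pytest.fixture(scope="session")
def clean_data(batch_trajectories):
    """Noise-free 10-point dataset from the default design."""
    return generate_dataset(batch_trajectories, 10,
                            NoiseSpec(kind="none", cv=0.0), seed=1)


@pytest.fixture(scope="session")
def phenom_truth():
    return PhenomParams(mu_g=0.22, K_g=6.0, mu_c=0.05, K_c=12.0, Y_xg=0.04,
                        Y_mx=2.0, beta=0.3, k_cr=5.0)


@pytest.fixture(scope="session")
def phenom_clean_data(phenom_truth):
    """Noise-free data generated by the phenomenological model itself."""
    t10 = np.linspace(0.0, 72.0, 10)
    conds = [(0.01, 60.0, 30.0, 0.0), (0.01, 52.0, 26.0, 0.0),
             (0.01, 68.0, 34.0, 0.0)]
    obs = np.empty((3, 10, 4))
    for i, c in enumerate(conds):
        obs[i] = simulate_phenom(phenom_truth, c, SpikeSchedule.batch(72.0),
                                 output_grid=t10).states
    return MeasurementDataset(conditions=obs[:, 0, :], times=t10,
                              observations=obs, noise=NoiseSpec(kind="none", cv=0.0))


@pytest.fixture(scope="session")
def oracle_growth(batch_trajectories, clean_data):
    """Effective growth rate (dXt/dt)/Xt of the dense truth, at the
    measurement nodes; the oracle for growth-rate recovery checks."""
    t10 = clean_data.times
    rows = []
    for tr in batch_trajectories:
        mu = np.gradient(tr["Xt"], tr.times) / tr["Xt"]
        rows.append(np.interp(t10, tr.times, mu))
    return np.array(rows)


@pytest.fixture(scope="session")
def study_results():
    """Full smoke-profile studies for the three acceptance seeds."""
    from hybridkin.study import build_study

    return {seed: build_study(smoke_config(seed=seed)) for seed in STUDY_SEEDS}


@pytest.fixture(scope="session")
def versatility_results():
    """Integrated-vs-blackbox comparison under the scaled-maintenance truth."""
    from hybridkin.study import (
        build_study,
    )

    results = {}
    for seed in STUDY_SEEDS:
        cfg = smoke_config(seed=seed, maintenance_scale=40.0)
        results[seed] = build_study(cfg, models=("integrated", "blackbox"))
    return results
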
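"""Phenomenological competitor model: Monod growth net of catechol inhibition.

The model tracks only the four observable states.  Total biomass grows at
``mu_PM = mu_g*Cg/(Cg+K_g) - mu_c*Cc/(Cc+K_c)`` — a net rate mixing growth
promotion by glucose and inhibition by catechol — and the product equations
mirror the ground truth with ``Xt`` standing in for viable biomass.  Its
eight parameters are estimated by multistart least squares subject to the
collocation-transcribed dynamics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .data import OBS_SPECIES, MeasurementDataset, SpikeSchedule, StateTrajectory
from .dynopt.collocation import CollocationGrid, CollocationProblem, ParamMap
from .dynopt.solve import MultistartConfig, solve_multistart
from .ground_truth import _piecewise_simulate
from .results import FitResult

PHENOM_PARAM_NAMES = ("mu_g", "K_g", "mu_c", "K_c", "Y_xg", "Y_mx", "beta", "k_cr")


@dataclass(frozen=True)
class PhenomParams:
    """Kinetic constants of the phenomenological model (all non-negative)."""

    mu_g: float
    K_g: float
    mu_c: float
    K_c: float
    Y_xg: float
    Y_mx: float
    beta: float
    k_cr: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"parameter {name} must be non-negative, got {value}")

    def as_dict(self) -> dict:
        return asdict(self)


def phenom_rhs(y, theta, mu=None):
    """Vectorised RHS on the canonical (Xt, Cg, Cc, Cm) state; ``mu`` unused."""
    Xt, Cg, Cc, Cm = (y[..., i] for i in range(4))
    mu_pm = (
        theta["mu_g"] * Cg / (Cg + theta["K_g"])
        - theta["mu_c"] * Cc / (Cc + theta["K_c"])
    )
    dXt = mu_pm * Xt
    dCg = -(mu_pm / theta["Y_xg"]) * Xt
    dCm = (theta["Y_mx"] * mu_pm + theta["beta"]) * Xt * Cc / (Cc + theta["k_cr"])
    return np.stack([dXt, dCg, -dCm, dCm], axis=-1)


def rhs_phenom(state, params: PhenomParams) -> np.ndarray:
    """Derivatives of (Xt, Cg, Cc, Cm) at a single observable state."""
    state = np.asarray(state, float)
    if np.any(state < 0):
        bad = OBS_SPECIES[int(np.argmin(state))]
        raise ValueError(f"negative state component {bad}")
    return phenom_rhs(state, params.as_dict())


def simulate_phenom(
    params: PhenomParams,
    init,
    schedule: SpikeSchedule,
    output_grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> StateTrajectory:
    """Integrate the phenomenological model with fed-batch spike events."""
    if output_grid is None:
        output_grid = np.linspace(0.0, schedule.horizon, 289)
    theta = params.as_dict()
    init = np.asarray(init, float)

    def rhs(t, y):
        return phenom_rhs(np.asarray(y, float), theta)

    impulse = np.array([0.0, schedule.cg_in, schedule.cc_in, 0.0])
    states = _piecewise_simulate(rhs, init, schedule, output_grid, impulse,
                                 rtol=rtol, atol=atol, strict_nonneg=False)
    return StateTrajectory(np.asarray(output_grid, float), states, OBS_SPECIES,
                           {"model": "phenom", "schedule": schedule.__dict__.copy()})


def _param_guesses(data: MeasurementDataset) -> dict:
    """Order-of-magnitude parameter guesses read off the training data."""
    obs = data.observations
    t = data.times
    Xt = np.clip(obs[..., 0], 1e-6, None)
    dln = np.diff(np.log(Xt), axis=1) / np.diff(t)
    g_max = max(float(np.max(dln)), 1e-3)
    cg_med = max(float(np.median(obs[..., 1])), 1.0)
    cc_med = max(float(np.median(obs[..., 2])), 1.0)
    dXt = obs[..., 0].max(axis=1) - obs[..., 0][:, 0]
    dCg = np.clip(obs[..., 1][:, 0] - obs[..., 1].min(axis=1), 1e-6, None)
    y_xg = max(float(np.median(dXt / dCg)), 1e-4)
    dCm = np.clip(obs[..., 3].max(axis=1) - obs[..., 3][:, 0], 1e-6, None)
    y_mx = max(float(np.median(dCm / np.clip(dXt, 1e-6, None))), 1e-3)
    beta = max(float(np.median(dCm) / (np.mean(obs[..., 0]) * (t[-1] - t[0]))), 1e-4)
    return {
        "mu_g": g_max,
        "K_g": cg_med / 5.0,
        "mu_c": g_max / 3.0,
        "K_c": cc_med / 2.0,
        "Y_xg": y_xg,
        "Y_mx": y_mx,
        "beta": beta,
        "k_cr": cc_med / 2.0,
    }


def phenom_problem(data: MeasurementDataset, grid: CollocationGrid | None = None):
    """Transcribed estimation problem + log-uniform start sampler for it."""
    guesses = _param_guesses(data)
    hi = np.array([guesses[n] for n in PHENOM_PARAM_NAMES]) * 30.0
    pmap = ParamMap(tiv_names=PHENOM_PARAM_NAMES,
                    tiv_lo=np.zeros(len(PHENOM_PARAM_NAMES)), tiv_hi=hi)
    problem = CollocationProblem(phenom_rhs, data, pmap, grid=grid)
    lo_box = np.array([guesses[n] for n in PHENOM_PARAM_NAMES]) / 3.0
    hi_box = lo_box * 10.0  # decade-wide log-uniform boxes around the guesses

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo_box), np.log(hi_box)))

    return problem, sampler


def fit_phenom(data: MeasurementDataset,
               config: MultistartConfig | None = None,
               grid: CollocationGrid | None = None) -> FitResult:
    """Estimate the eight phenomenological parameters from a dataset.

    Raises a degenerate-data error when the dataset shows no growth at all
    (all-zero biomass), which leaves every rate unidentifiable.
    """
    if np.all(data.observations[..., 0] <= 0):
        raise ValueError("degenerate dataset: biomass is identically zero; "
                         "growth parameters are not identifiable")
    config = config or MultistartConfig()
    problem, sampler = phenom_problem(data, grid=grid)
    res = solve_multistart(problem, sampler, config)
    return FitResult(
        model="phenom",
        tiv=res.tiv,
        objective=res.objective,
        start_log=res.start_log,
        seed=config.seed,
    )
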
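"""Ground-truth bioprocess model and synthetic dataset generation.

The simulated system is an engineered *Pseudomonas putida* culture growing
on glucose while converting catechol — a cytotoxic lignin-derived aromatic —
into cis,cis-muconic acid (MA).  Six states are tracked: viable biomass
``Xv`` and dead biomass ``Xd`` (OD600), glucose ``Cg``, catechol ``Cc`` and
muconic acid ``Cm`` (mM), with total biomass ``Xt = Xv + Xd`` as the derived
observable.  The kinetic structure:

* viable cells grow at a logistic-Monod rate
  ``mu_gr = (1 - Xv/(Y_xg*Cg0)) * mu_g * Cg/(Cg + K_g)``, reproducing the
  lag/exponential/stationary phases of a batch culture;
* cells die at ``mu_dt = k_d + mu_c * Cc/(Cc + K_c)``, a zero-order term
  plus a catechol-toxicity Monod term; dead cells are not degraded and
  accumulate in ``Xt``;
* glucose is consumed by growth (``mu_gr/Y_xg``) and by a maintenance term
  ``m_k * Cc/(Cc + k_cm)`` that models the energetic cost of neutralising
  catechol toxicity;
* MA is produced from catechol with growth-associated (``Y_mx * mu_gr``)
  and non-growth-associated (``beta``) components, saturating in catechol;
  every mole of catechol consumed becomes MA (``dCc/dt = -dCm/dt``).

Fed-batch operation adds periodic concentration impulses of glucose and
catechol (see :class:`~hybridkin.data.SpikeSchedule`); between impulses the
dynamics are the batch ODEs, so integration proceeds piecewise with a state
jump at each spike time.

No kinetic constants for this strain/process are established in the
literature; the committed :func:`default_params` are repository-chosen
values calibrated so a 72 h batch from mid-range initial conditions shows
the expected qualitative course: sigmoidal biomass with a lag, glucose
near-depletion, and most catechol converted to MA by harvest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from .data import (
    FULL_SPECIES,
    OBS_SPECIES,
    MeasurementDataset,
    NoiseSpec,
    SpikeSchedule,
    StateTrajectory,
)

#: integration order of the latent state vector
GT_STATE: tuple[str, ...] = ("Xv", "Xd", "Cg", "Cc", "Cm")

_NEG_TOL = 1e-7  # values in (-_NEG_TOL, 0) are clipped; worse is an error


@dataclass(frozen=True)
class GroundTruthParams:
    """Kinetic constants of the ground-truth model.

    Attributes
    ----------
    mu_g : float
        Maximum specific growth rate, 1/h.
    K_g : float
        Glucose half-saturation for growth, mM.
    k_d : float
        Zero-order (catechol-independent) death rate, 1/h.
    mu_c : float
        Maximum catechol-dependent death rate, 1/h.
    K_c : float
        Catechol half-saturation for the toxic death term, mM.
    Y_xg : float
        Biomass yield on glucose, OD600/mM; also sets the logistic carrying
        capacity ``Y_xg * Cg0``.
    m_k : float
        Maintenance glucose demand tied to catechol detoxification,
        mM glucose/(OD600 h).
    k_cm : float
        Catechol half-saturation of the maintenance term, mM.
    k_mg : float
        Glucose half-saturation regularising the maintenance term, mM.  The
        maintenance demand is multiplied by ``Cg/(Cg + k_mg)`` so that it
        shuts off smoothly as glucose runs out; without it the
        glucose-independent maintenance term would drive ``Cg`` negative.
    Y_mx : float
        Growth-associated MA yield, mM/OD600.
    beta : float
        Non-growth-associated MA production rate, mM/(OD600 h).
    k_cr : float
        Catechol half-saturation for MA production, mM.
    maintenance_scale : float
        Dimensionless multiplier on ``m_k``; raised well above 1 in the
        "versatility" variant where maintenance consumes as much glucose as
        growth does.
    """

    mu_g: float = 0.25
    K_g: float = 5.0
    k_d: float = 0.005
    mu_c: float = 0.04
    K_c: float = 15.0
    Y_xg: float = 0.04
    m_k: float = 0.1
    k_cm: float = 5.0
    k_mg: float = 0.5
    Y_mx: float = 2.0
    beta: float = 0.35
    k_cr: float = 5.0
    maintenance_scale: float = 1.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"parameter {name} must be non-negative, got {value}")


@dataclass(frozen=True)
class GroundTruthState:
    """A single latent culture state; ``Xt`` is derived as ``Xv + Xd``."""

    Xv: float
    Xd: float
    Cg: float
    Cc: float
    Cm: float

    @property
    def Xt(self) -> float:
        return self.Xv + self.Xd

    def as_array(self) -> np.ndarray:
        return np.array([self.Xv, self.Xd, self.Cg, self.Cc, self.Cm])

    @classmethod
    def from_array(cls, arr) -> "GroundTruthState":
        return cls(*np.asarray(arr, float))

    def __post_init__(self) -> None:
        for name in GT_STATE:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be non-negative")


def default_params() -> GroundTruthParams:
    """The committed repository-default ground-truth parameter set."""
    return GroundTruthParams()


def versatility_params(scale: float = 40.0) -> GroundTruthParams:
    """Variant with maintenance scaled up to rival growth-linked consumption.

    With the default ``m_k`` the maintenance term is a minor contributor to
    glucose consumption.  Scaling it by ``scale`` makes the cumulative
    maintenance draw comparable to the growth-related draw over a default
    batch, changing the physics that the fitted models never saw.
    """
    return replace(default_params(), maintenance_scale=scale)


def gt_rates(Xv, Cg, Cc, params: GroundTruthParams, Cg0: float):
    """Growth and death rates (``mu_gr``, ``mu_dt``); broadcast- and complex-safe."""
    mu_gr = (1.0 - Xv / (params.Y_xg * Cg0)) * params.mu_g * Cg / (Cg + params.K_g)
    mu_dt = params.k_d + params.mu_c * Cc / (Cc + params.K_c)
    return mu_gr, mu_dt


def gt_rhs(y, params: GroundTruthParams, Cg0: float):
    """Vectorised RHS for state array ``y`` with last axis (Xv, Xd, Cg, Cc, Cm)."""
    Xv, Xd, Cg, Cc, Cm = (y[..., i] for i in range(5))
    mu_gr, mu_dt = gt_rates(Xv, Cg, Cc, params, Cg0)
    maint = (
        params.maintenance_scale
        * params.m_k
        * Cc
        / (Cc + params.k_cm)
        * Cg
        / (Cg + params.k_mg)
    )
    dXv = (mu_gr - mu_dt) * Xv
    dXd = mu_dt * Xv
    dCg = -(mu_gr / params.Y_xg + maint) * Xv
    dCm = (params.Y_mx * mu_gr + params.beta) * Xv * Cc / (Cc + params.k_cr)
    dCc = -dCm
    return np.stack([dXv, dXd, dCg, dCc, dCm], axis=-1)


def rhs_ground_truth(
    state: GroundTruthState, params: GroundTruthParams, Cg0: float
) -> np.ndarray:
    """Time derivatives of (Xv, Xd, Cg, Cc, Cm) for a single state.

    ``Cg0`` is the capacity-reference glucose concentration appearing in the
    logistic factor; it is fixed at the t=0 glucose level and not updated on
    fed-batch spikes.
    """
    if Cg0 <= 0:
        raise ValueError("capacity reference Cg0 must be positive")
    arr = state.as_array()
    for name, v in zip(GT_STATE, arr):
        if v < 0:
            raise ValueError(f"negative state component {name}: {v}")
    return gt_rhs(arr, params, Cg0)


def _clip_small_negatives(y: np.ndarray, context: str) -> np.ndarray:
    bad = y < -_NEG_TOL
    if np.any(bad):
        raise RuntimeError(f"negative state beyond tolerance during {context}: min={y.min():.3e}")
    return np.clip(y, 0.0, None)


def _piecewise_simulate(
    rhs,
    y0: np.ndarray,
    schedule: SpikeSchedule,
    output_grid: np.ndarray,
    impulse: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
    strict_nonneg: bool = True,
    events=None,
) -> np.ndarray:
    """Integrate ``rhs`` piecewise between spike events.

    ``impulse`` is the per-state jump applied at every spike time.  Output
    rows at a spike time hold the post-impulse value.  Shared by the
    ground-truth, phenomenological and hybrid simulators; the ground truth
    enforces non-negative states (``strict_nonneg``) while fitted models are
    allowed to predict negative concentrations (a model error that the
    evaluation metrics penalise).
    """
    grid = np.asarray(output_grid, float)
    if np.any(grid < -1e-12) or np.any(grid > schedule.horizon + 1e-9):
        raise ValueError("output grid must lie within [0, horizon]")
    spikes = schedule.spike_times
    interior = spikes[spikes < schedule.horizon - 1e-9]
    terminal = spikes[np.isclose(spikes, schedule.horizon)]
    boundaries = np.concatenate([[0.0], interior, [schedule.horizon]])

    out = np.empty((grid.size, y0.size))
    y = np.array(y0, float)
    for k in range(boundaries.size - 1):
        t0, t1 = boundaries[k], boundaries[k + 1]
        last = k == boundaries.size - 2
        sol = solve_ivp(rhs, (t0, t1), y, method=method, dense_output=True,
                        rtol=rtol, atol=atol, events=events)
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{t0}, {t1}], last good t={sol.t[-1]}: {sol.message}"
            )
        if sol.status == 1:  # a terminal event fired: divergence guard
            raise RuntimeError(
                f"simulation terminated by guard event at t={sol.t[-1]:.2f}"
            )
        if last:
            mask = (grid >= t0 - 1e-9) & (grid <= t1 + 1e-9)
        else:
            mask = (grid >= t0 - 1e-9) & (grid < t1 - 1e-9)
        if mask.any():
            vals = sol.sol(np.clip(grid[mask], t0, t1)).T
            out[mask] = _clip_small_negatives(vals, "simulation") if strict_nonneg else vals
        y = sol.y[:, -1]
        if strict_nonneg:
            y = _clip_small_negatives(y, "simulation")
        if not last:
            y = y + impulse
            hit = np.isclose(grid, t1)
            if hit.any():  # spike-time rows record the post-impulse value
                out[hit] = y
    if terminal.size:
        y = y + impulse
        hit = np.isclose(grid, schedule.horizon)
        if hit.any():
            out[hit] = y
    return out


def simulate(
    params: GroundTruthParams,
    init: GroundTruthState,
    schedule: SpikeSchedule,
    output_grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> StateTrajectory:
    """Simulate the ground-truth model over ``schedule.horizon`` hours.

    Returns a :class:`StateTrajectory` carrying (Xt, Cg, Cc, Cm, Xv, Xd).
    The logistic capacity reference is the initial glucose concentration and
    is left unchanged by spikes.
    """
    if output_grid is None:
        output_grid = np.linspace(0.0, schedule.horizon, 289)
    Cg0 = init.Cg
    if Cg0 <= 0:
        raise ValueError("initial glucose must be positive (capacity reference)")

    def rhs(t, y):
        return gt_rhs(np.asarray(y, float), params, Cg0)

    impulse = np.array([0.0, 0.0, schedule.cg_in, schedule.cc_in, 0.0])
    raw = _piecewise_simulate(rhs, init.as_array(), schedule, output_grid, impulse,
                              rtol=rtol, atol=atol)
    Xv, Xd, Cg, Cc, Cm = raw.T
    states = np.column_stack([Xv + Xd, Cg, Cc, Cm, Xv, Xd])
    return StateTrajectory(
        times=np.asarray(output_grid, float),
        states=states,
        species=FULL_SPECIES,
        metadata={
            "init": init.as_array().tolist(),
            "schedule": schedule.__dict__.copy(),
            "Cg0": Cg0,
        },
    )


def sample_initial_conditions(
    n: int,
    glucose_range: tuple[float, float] = (50.0, 70.0),
    catechol_range: tuple[float, float] = (25.0, 35.0),
    biomass: float = 0.01,
    seed: int | None = None,
) -> list[GroundTruthState]:
    """Latin-hypercube sample of initial (glucose, catechol) conditions.

    All cultures start fully viable at the given biomass with no MA.  The
    default ranges and the 0.01 OD600 inoculum are the training-design
    conditions of the study.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for lo, hi in (glucose_range, catechol_range):
        if not lo < hi:
            raise ValueError("ranges must satisfy lo < hi")
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, [glucose_range[0], catechol_range[0]],
                       [glucose_range[1], catechol_range[1]])
    return [
        GroundTruthState(Xv=biomass, Xd=0.0, Cg=float(g), Cc=float(c), Cm=0.0)
        for g, c in scaled
    ]


def generate_dataset(
    trajectories: list[StateTrajectory],
    n_points: int = 10,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> MeasurementDataset:
    """Sample trajectories at a sparse uniform grid and corrupt with noise.

    Only the four observable species (Xt, Cg, Cc, Cm) are retained.  The
    measurement grid is ``n_points`` uniformly spaced times including t=0
    and the horizon.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    horizons = {float(tr.times[-1]) for tr in trajectories}
    if len(horizons) != 1:
        raise ValueError("all trajectories must share the same horizon")
    horizon = horizons.pop()
    grid = np.linspace(0.0, horizon, n_points)
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    obs = np.empty((len(trajectories), n_points, len(OBS_SPECIES)))
    for i, tr in enumerate(trajectories):
        obs[i] = tr.at(grid, OBS_SPECIES)
    noisy = noise.apply(obs, rng)
    return MeasurementDataset(
        conditions=noisy[:, 0, :].copy(),
        times=grid,
        observations=noisy,
        noise=noise,
        seed=seed,
    )
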
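"""Shared data containers: trajectories, spike schedules and measurement datasets.

Canonical observable species order is ``("Xt", "Cg", "Cc", "Cm")`` — total
biomass (OD600), glucose, catechol and muconic acid (all concentrations in
mM).  The ground-truth simulator additionally tracks the latent split of
total biomass into viable (``Xv``) and dead (``Xd``) fractions; measurement
datasets never contain those columns, mirroring the practical fact that
optical density cannot distinguish live from dead cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical observable species, also the CSV column order
OBS_SPECIES: tuple[str, ...] = ("Xt", "Cg", "Cc", "Cm")

#: latent + observable species stored for ground-truth trajectories
FULL_SPECIES: tuple[str, ...] = ("Xt", "Cg", "Cc", "Cm", "Xv", "Xd")


@dataclass(frozen=True)
class SpikeSchedule:
    """Impulsive fed-batch substrate additions with fixed period.

    Glucose (``cg_in``) and catechol (``cc_in``) are added as instantaneous
    concentration jumps at times ``tau, 2*tau, ...`` up to ``horizon``.  The
    dose nominally delivered at t=0 is considered part of the initial
    condition and is never applied as a spike.

    Parameters
    ----------
    cg_in : float
        Glucose impulse magnitude, mM per spike.
    cc_in : float
        Catechol impulse magnitude, mM per spike.
    tau : float
        Spike period, h.  Must be positive.
    horizon : float
        Simulation end time, h.
    """

    cg_in: float = 0.0
    cc_in: float = 0.0
    tau: float = 25.0
    horizon: float = 72.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("spike period tau must be positive")
        if self.cg_in < 0 or self.cc_in < 0:
            raise ValueError("impulse magnitudes must be non-negative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def spike_times(self) -> np.ndarray:
        """Times at which impulses are applied (tau, 2*tau, ... <= horizon)."""
        if self.cg_in == 0.0 and self.cc_in == 0.0:
            return np.empty(0)
        n = int(np.floor(self.horizon / self.tau + 1e-12))
        times = self.tau * np.arange(1, n + 1)
        return times[times <= self.horizon + 1e-12]

    @classmethod
    def batch(cls, horizon: float = 72.0) -> "SpikeSchedule":
        """A pure batch schedule (no feed) over ``horizon`` hours."""
        return cls(cg_in=0.0, cc_in=0.0, tau=horizon, horizon=horizon)


@dataclass
class StateTrajectory:
    """Dense time-indexed state values of one simulated culture.

    ``states`` has shape ``(len(times), len(species))``; the stored value at
    a spike time is the post-impulse one (left limit plus the impulse).
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValueError("states shape inconsistent with times/species")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def at(self, t: np.ndarray, species: tuple[str, ...] | None = None) -> np.ndarray:
        """Linear interpolation of (a subset of) the states at times ``t``."""
        sp = self.species if species is None else species
        t = np.atleast_1d(np.asarray(t, float))
        out = np.empty((t.size, len(sp)))
        for j, name in enumerate(sp):
            out[:, j] = np.interp(t, self.times, self[name])
        return out

    def observable(self) -> "StateTrajectory":
        """Restrict to the four measurable species."""
        cols = [self.species.index(s) for s in OBS_SPECIES]
        return StateTrajectory(self.times, self.states[:, cols], OBS_SPECIES, dict(self.metadata))

    def to_frame(self, condition_id: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time_h", self.times)
        df.insert(0, "condition_id", condition_id)
        return df


@dataclass
class NoiseSpec:
    """Measurement-noise description: multiplicative Gaussian with given CV.

    Each observation y is replaced by ``y * (1 + cv * eps)`` with
    ``eps ~ N(0, 1)``, then clipped at zero.  ``cv=0`` disables noise.
    """

    kind: str = "multiplicative_gaussian"
    cv: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.cv == 0.0:
            return np.array(values, float)
        noisy = values * (1.0 + self.cv * rng.standard_normal(values.shape))
        return np.clip(noisy, 0.0, None)


@dataclass
class MeasurementDataset:
    """Sparse noisy observations of (Xt, Cg, Cc, Cm) for several conditions.

    ``observations`` has shape ``(n_conditions, n_times, 4)`` in the
    canonical :data:`OBS_SPECIES` order; ``conditions`` holds the known
    initial observable state per condition, shape ``(n_conditions, 4)``.
    """

    conditions: np.ndarray
    times: np.ndarray
    observations: np.ndarray
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.conditions = np.atleast_2d(np.asarray(self.conditions, float))
        self.times = np.asarray(self.times, float)
        self.observations = np.asarray(self.observations, float)
        n, t = self.conditions.shape[0], self.times.size
        if self.observations.shape != (n, t, len(OBS_SPECIES)):
            raise ValueError(
                f"observations must have shape {(n, t, len(OBS_SPECIES))}, "
                f"got {self.observations.shape}"
            )

    @property
    def n_conditions(self) -> int:
        return self.conditions.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    def species_scale(self) -> np.ndarray:
        """Per-species maximum over the dataset, used to normalise errors."""
        scale = np.abs(self.observations).max(axis=(0, 1))
        return np.where(scale > 0, scale, 1.0)

    def subset(self, condition_ids) -> "MeasurementDataset":
        ids = np.atleast_1d(condition_ids)
        return MeasurementDataset(
            self.conditions[ids], self.times, self.observations[ids], self.noise, self.seed
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_conditions):
            df = pd.DataFrame(self.observations[i], columns=list(OBS_SPECIES))
            df.insert(0, "time_h", self.times)
            df.insert(0, "condition_id", i)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeasurementDataset":
        ids = sorted(df["condition_id"].unique())
        times = np.sort(df.loc[df["condition_id"] == ids[0], "time_h"].to_numpy())
        obs = np.empty((len(ids), times.size, len(OBS_SPECIES)))
        for i, cid in enumerate(ids):
            sub = df[df["condition_id"] == cid].sort_values("time_h")
            if not np.allclose(sub["time_h"].to_numpy(), times):
                raise ValueError("all conditions must share the same time grid")
            obs[i] = sub[list(OBS_SPECIES)].to_numpy()
        return cls(conditions=obs[:, 0, :].copy(), times=times, observations=obs)

    @classmethod
    def from_csv(cls, path) -> "MeasurementDataset":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self) -> str:
        return json.dumps(
            {
                "conditions": self.conditions.tolist(),
                "times": self.times.tolist(),
                "observations": self.observations.tolist(),
                "noise": {"kind": self.noise.kind, "cv": self.noise.cv},
                "seed": self.seed,
            }
        )
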
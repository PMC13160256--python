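"""Run configuration: every knob of the end-to-end study in one artifact.

A :class:`RunConfig` fully determines a study — ground-truth variant,
training design, noise, estimation settings, evaluation grid — and
round-trips through YAML/JSON, so any run is reproducible from its config
file and seed alone.  Two profiles bundle sensible sizes: ``smoke`` (small
multistart, fixed architectures, 5x5 evaluation grid; minutes on one CPU)
and ``paper`` (50-start multistart, cross-validated architectures, full
9x11 grid).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    profile: str = "smoke"

    # ground truth variant
    maintenance_scale: float = 1.0

    # training design (Latin hypercube over initial concentrations)
    n_conditions: int = 3
    glucose_range: tuple[float, float] = (50.0, 70.0)
    catechol_range: tuple[float, float] = (25.0, 35.0)
    biomass: float = 0.01

    # measurement model
    horizon: float = 72.0
    n_points: int = 10
    noise_cv: float = 0.05

    # fed-batch evaluation schedule
    cg_in: float = 10.0
    cc_in: float = 3.0
    tau: float = 25.0

    # estimation
    n_starts: int = 5
    max_nfev: int = 150
    w_s: float = 10.0
    hidden: tuple[int, ...] = (4,)
    use_cv: bool = False
    fit_nsub: int = 1

    # evaluation grid
    eval_glucose: tuple[float, float, int] = (20.0, 100.0, 5)
    eval_catechol: tuple[float, float, int] = (5.0, 55.0, 5)
    n_eval_times: int = 10

    def __post_init__(self) -> None:
        if self.profile not in ("smoke", "paper", "custom"):
            raise ValueError(f"unknown profile {self.profile!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("glucose_range", "catechol_range", "hidden",
                  "eval_glucose", "eval_catechol"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("glucose_range", "catechol_range", "hidden",
                  "eval_glucose", "eval_catechol"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def smoke_config(seed: int = 0, **overrides) -> RunConfig:
    """Small-but-complete profile: fixed architectures, 3-start multistart,
    5x5 evaluation grid; the full study finishes in minutes on one CPU."""
    return RunConfig(seed=seed, profile="smoke", **overrides)


def paper_config(seed: int = 0, **overrides) -> RunConfig:
    """Full-size profile: 50-start multistart, cross-validated smoothing
    weight and architectures, 9x11 evaluation grid."""
    defaults = dict(
        n_starts=50,
        max_nfev=300,
        use_cv=True,
        fit_nsub=2,
        eval_glucose=(20.0, 100.0, 9),
        eval_catechol=(5.0, 55.0, 11),
    )
    defaults.update(overrides)
    return RunConfig(seed=seed, profile="paper", **defaults)
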
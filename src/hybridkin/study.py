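"""End-to-end study: data generation, all five model fits, fed-batch
extrapolation scoring and attribution, with resumable on-disk artifacts.

``build_study`` runs everything in memory and returns a
:class:`StudyResult`; ``run_study`` wraps it with a workspace of CSV/JSON/
PNG artifacts, skipping any stage whose artifact already exists.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .attribution import attribution_table
from .blackbox import BlackboxModel, train_blackbox
from .config import RunConfig
from .data import MeasurementDataset, NoiseSpec, SpikeSchedule
from .dynopt.collocation import CollocationGrid
from .dynopt.solve import MultistartConfig
from .evaluation import (
    EvaluationGrid,
    blackbox_predictor,
    distribution_summary,
    evaluate_grid,
    hybrid_predictor,
    phenom_predictor,
    plot_heatmaps,
    region_summary,
)
from .ground_truth import (
    GroundTruthParams,
    default_params,
    generate_dataset,
    sample_initial_conditions,
    simulate,
)
from .hybrid import (
    DEFAULT_ARCH_GRID,
    fit_improved,
    fit_integrated,
    fit_sequential,
)
from .phenom import fit_phenom
from .results import FitResult

MODEL_NAMES = ("phenom", "sequential", "integrated", "improved", "blackbox")


@dataclass
class StudyResult:
    config: RunConfig
    data: MeasurementDataset
    fits: dict
    grid: EvaluationGrid | None = None
    timings: dict = field(default_factory=dict)

    def mean_r2(self) -> dict:
        if self.grid is None:
            return {}
        return {name: self.grid.mean_r2(name) for name in self.grid.models}


def ground_truth_params(config: RunConfig) -> GroundTruthParams:
    return replace(default_params(), maintenance_scale=config.maintenance_scale)


def generate_study_data(config: RunConfig) -> MeasurementDataset:
    """Training data: batch cultures from the Latin-hypercube design,
    sampled sparsely and corrupted with multiplicative noise."""
    params = ground_truth_params(config)
    inits = sample_initial_conditions(
        config.n_conditions, config.glucose_range, config.catechol_range,
        config.biomass, seed=config.seed,
    )
    schedule = SpikeSchedule.batch(config.horizon)
    trajectories = [simulate(params, ic, schedule) for ic in inits]
    noise = (NoiseSpec(cv=config.noise_cv) if config.noise_cv > 0
             else NoiseSpec(kind="none", cv=0.0))
    return generate_dataset(trajectories, config.n_points, noise,
                            seed=config.seed + 1)


def fit_all(config: RunConfig, data: MeasurementDataset,
            models=MODEL_NAMES) -> tuple[dict, dict]:
    """Fit the requested model families; returns (fits, timings)."""
    grid = CollocationGrid.for_data(data, K=5, nsub=config.fit_nsub)
    ms = MultistartConfig(n_starts=config.n_starts, seed=config.seed + 2,
                          max_nfev=config.max_nfev)
    arch_grid = DEFAULT_ARCH_GRID if config.use_cv else None
    fits: dict = {}
    timings: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        fits[name] = fn()
        timings[name] = time.perf_counter() - t0

    if "phenom" in models:
        stage("phenom", lambda: fit_phenom(data, config=ms, grid=grid))
    if "sequential" in models:
        stage("sequential", lambda: fit_sequential(
            data, w_s=None if config.use_cv else config.w_s,
            arch_grid=arch_grid, config=ms, grid=grid, seed=config.seed + 3,
        ))
    if "integrated" in models:
        stage("integrated", lambda: fit_integrated(
            data, hidden=config.hidden, arch_grid=arch_grid, config=ms,
            grid=grid,
        ))
    if "improved" in models:
        stage("improved", lambda: fit_improved(
            data, hidden=config.hidden, arch_grid=arch_grid, config=ms,
            grid=grid,
        ))
    if "blackbox" in models:
        bb_grid = None if config.use_cv else [
            {"hidden": (8,), "activation": "tanh", "alpha": 1e-4},
            {"hidden": (16,), "activation": "tanh", "alpha": 1e-4},
            {"hidden": (8,), "activation": "relu", "alpha": 1e-4},
            {"hidden": (16,), "activation": "relu", "alpha": 1e-4},
        ]
        stage("blackbox", lambda: train_blackbox(
            data, arch_grid=bb_grid, seed=config.seed + 4,
        ))
    return fits, timings


def predictors(fits: dict) -> dict:
    out = {}
    for name, fit in fits.items():
        if name == "phenom":
            out[name] = phenom_predictor(fit)
        elif name == "blackbox":
            out[name] = blackbox_predictor(fit)
        else:
            out[name] = hybrid_predictor(fit)
    return out


def evaluate_study(config: RunConfig, fits: dict) -> EvaluationGrid:
    """Fed-batch extrapolation grid for all fitted models."""
    params = ground_truth_params(config)
    schedule = SpikeSchedule(cg_in=config.cg_in, cc_in=config.cc_in,
                             tau=config.tau, horizon=config.horizon)
    g_lo, g_hi, g_n = config.eval_glucose
    c_lo, c_hi, c_n = config.eval_catechol
    return evaluate_grid(
        predictors(fits),
        params,
        glucose_axis=np.linspace(g_lo, g_hi, int(g_n)),
        catechol_axis=np.linspace(c_lo, c_hi, int(c_n)),
        schedule=schedule,
        eval_times=np.linspace(0.0, config.horizon, config.n_eval_times),
        biomass=config.biomass,
        seed=config.seed,
    )


def attribution_summary(fit: FitResult, data: MeasurementDataset,
                        n_steps: int = 128) -> dict:
    """Mean Integrated-Gradients score per input over all training points."""
    points = data.observations.reshape(-1, data.observations.shape[-1])
    _, means = attribution_table(fit.ann, points, n_steps=n_steps)
    names = fit.ann.input_names or tuple(f"x{i}" for i in range(means.size))
    return dict(zip(names, (float(v) for v in means)))


def build_study(config: RunConfig, models=MODEL_NAMES) -> StudyResult:
    """Run the full study in memory: data, fits, evaluation grid."""
    data = generate_study_data(config)
    fits, timings = fit_all(config, data, models=models)
    grid = evaluate_study(config, fits)
    return StudyResult(config=config, data=data, fits=fits, grid=grid,
                       timings=timings)


# --------------------------------------------------------------------------
# on-disk workspace
# --------------------------------------------------------------------------
def run_study(config: RunConfig, outdir, force: bool = False) -> StudyResult:
    """Run the study with resumable artifacts in ``outdir``.

    Stages (data, each fit, evaluation, attribution, report) are skipped
    when their artifact already exists, so an interrupted run resumes where
    it stopped.  Re-running with an unchanged config reproduces identical
    artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    data_path = outdir / "training_data.csv"
    if data_path.exists() and not force:
        data = MeasurementDataset.from_csv(data_path)
    else:
        data = generate_study_data(config)
        data.to_csv(data_path)

    fits: dict = {}
    timings: dict = {}
    for name in MODEL_NAMES:
        path = outdir / f"fit_{name}.json"
        if path.exists() and not force:
            d = json.loads(path.read_text())
            fits[name] = (BlackboxModel.from_dict(d) if name == "blackbox"
                          else FitResult.from_dict(d))
            continue
        new_fits, t = fit_all(config, data, models=(name,))
        fits[name] = new_fits[name]
        timings.update(t)
        artifact = fits[name].to_dict()
        path.write_text(json.dumps(artifact, indent=1))

    grid_path = outdir / "evaluation_grid.csv"
    grid = evaluate_study(config, fits)
    grid.to_csv(grid_path)
    region_summary(grid).to_csv(outdir / "region_summary.csv", index=False)
    distribution_summary(grid).to_csv(outdir / "r2_distribution.csv", index=False)
    plot_heatmaps(grid, outdir / "r2_heatmaps.png")

    attr = attribution_summary(fits["integrated"], data)
    with open(outdir / "attribution_integrated.csv", "w") as fh:
        fh.write("input_name,attribution\n")
        for k, v in attr.items():
            fh.write(f"{k},{v}\n")

    report = {
        "config": config.to_dict(),
        "mean_R2": {name: grid.mean_r2(name) for name in grid.models},
        "attribution_integrated": attr,
        "n_failures": len(grid.failures),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return StudyResult(config=config, data=data, fits=fits, grid=grid,
                       timings=timings)
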
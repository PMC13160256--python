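"""Integrated-Gradients attribution for fitted networks.

For a network output F and baseline x', the attribution of input i at a
point x is

    IG_i = (x_i - x'_i) * ∫₀¹ ∂F/∂x_i (x' + α (x - x')) dα,

approximated by a midpoint Riemann sum; the gradients are exact (reverse-
mode differentiation of the network), so the completeness identity
Σ IG_i = F(x) - F(x') holds up to pure quadrature error, which the result
records as its ``completeness_gap``.

The default baseline is the training-data minimum of each input (the
all-zeros point of the network's scaled input space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynopt.ann import ANNSpec


@dataclass
class AttributionResult:
    """Signed per-input attribution scores at one input point."""

    attributions: np.ndarray
    inputs: np.ndarray
    baseline: np.ndarray
    n_steps: int
    value: float
    baseline_value: float
    input_names: tuple[str, ...] | None = None

    @property
    def completeness_gap(self) -> float:
        return float(abs(self.attributions.sum() - (self.value - self.baseline_value)))

    def to_frame(self) -> pd.DataFrame:
        names = self.input_names or tuple(
            f"x{i}" for i in range(self.attributions.size)
        )
        return pd.DataFrame(
            {"input_name": list(names), "attribution": self.attributions}
        )


def default_baseline(spec: ANNSpec) -> np.ndarray:
    """The all-zeros point of the scaled input space (training minima)."""
    return np.array(spec.input_offset, float)


def integrated_gradients(
    spec: ANNSpec,
    x,
    baseline=None,
    n_steps: int = 128,
    output: int = 0,
) -> AttributionResult:
    """Integrated-Gradients attribution of output ``output`` at point ``x``."""
    x = np.asarray(x, float)
    baseline = default_baseline(spec) if baseline is None else np.asarray(baseline, float)
    if x.shape != (spec.n_inputs,) or baseline.shape != (spec.n_inputs,):
        raise ValueError(
            f"x and baseline must have shape ({spec.n_inputs},), got {x.shape} "
            f"and {baseline.shape}"
        )
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8")
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    path = baseline[None, :] + alphas[:, None] * (x - baseline)[None, :]
    grads = spec.input_gradient(path)[:, output, :]  # (n_steps, n_inputs)
    attributions = (x - baseline) * grads.mean(axis=0)
    return AttributionResult(
        attributions=attributions,
        inputs=x,
        baseline=baseline,
        n_steps=n_steps,
        value=float(spec.forward(x)[..., output]),
        baseline_value=float(spec.forward(baseline)[..., output]),
        input_names=spec.input_names,
    )


def attribution_table(spec: ANNSpec, points, baseline=None, n_steps: int = 128):
    """Attributions at many points: array (n_points, n_inputs) plus means.

    The per-input mean over a set of training points is the primary
    attribution score reported for a fitted hybrid network.
    """
    points = np.atleast_2d(np.asarray(points, float))
    rows = np.empty_like(points)
    for i, pt in enumerate(points):
        rows[i] = integrated_gradients(spec, pt, baseline, n_steps).attributions
    return rows, rows.mean(axis=0)


def attribution_sweep(
    spec: ANNSpec,
    base_point,
    feature: int | str,
    grid,
    baseline=None,
    n_steps: int = 128,
) -> pd.DataFrame:
    """Vary one input over ``grid`` (others held at ``base_point``) and
    report the swept feature's own attribution at each value."""
    base_point = np.asarray(base_point, float)
    if isinstance(feature, str):
        if not spec.input_names or feature not in spec.input_names:
            raise ValueError(f"unknown feature {feature!r}")
        feature = spec.input_names.index(feature)
    vals, scores = [], []
    for v in np.asarray(grid, float):
        pt = base_point.copy()
        pt[feature] = v
        res = integrated_gradients(spec, pt, baseline, n_steps)
        vals.append(v)
        scores.append(res.attributions[feature])
    return pd.DataFrame({"feature_value": vals, "attribution": scores})
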
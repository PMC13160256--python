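"""Objective building blocks of the estimation NLPs.

Both functions accept arrays with arbitrary leading batch axes so they can
be evaluated on complex-step-perturbed decision variables.
"""

from __future__ import annotations

import numpy as np


def mse_objective(pred, act, scale=None):
    """State-space mean squared error over conditions x times x species.

    ``pred`` and ``act`` must share the trailing shape ``(N, t, S)``.  When
    ``scale`` (length S) is given each species' error is divided by it
    before squaring, making OD600-sized and mM-sized residuals
    commensurate; the default is unscaled.
    """
    pred = np.asarray(pred)
    act = np.asarray(act)
    if pred.shape[-3:] != act.shape[-3:]:
        raise ValueError(f"shape mismatch: {pred.shape} vs {act.shape}")
    n, t, s = act.shape[-3:]
    diff = pred - act
    if scale is not None:
        diff = diff / np.asarray(scale)
    return np.sum(diff**2, axis=(-3, -2, -1)) / (n * t * s)


def smoothness_penalty(theta_tv):
    """Mean squared second difference of time-variant parameter trajectories.

    ``theta_tv`` has trailing shape ``(N, t)`` (condition x measurement
    time); the penalty is ``(1/(N t)) * sum_i sum_j (theta[i,j+1] -
    2 theta[i,j] + theta[i,j-1])^2``.  Vanishes for trajectories that are
    constant or linear in the time index.
    """
    theta = np.asarray(theta_tv)
    n, t = theta.shape[-2:]
    if t < 3:
        raise ValueError("smoothness penalty needs at least 3 time points")
    d2 = theta[..., :, 2:] - 2.0 * theta[..., :, 1:-1] + theta[..., :, :-2]
    return np.sum(d2**2, axis=(-2, -1)) / (n * t)
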
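"""Radau collocation transcription of ODE estimation problems.

The estimation problems all share one shape: minimise a (weighted) state-
space MSE over measurement data, subject to the model ODEs imposed as Radau
IIA collocation equality constraints on finite elements aligned with the
measurement intervals, with optional time-variant parameters ``mu`` living
at measurement nodes (linearly interpolated inside an interval) that are
either free decision variables (TVPE) or tied to an embedded neural network
evaluated on the state at the node.

The transcribed problem is solved in *reduced space*: for any candidate
parameter vector the collocation equations are solved interval-by-interval
by Newton's method (they are square in the unknown node states), leaving a
small dense least-squares problem over the time-invariant parameters, the
time-variant parameter values and/or the network weights.  Exact Jacobians
of the measurement residuals with respect to the parameters follow from the
implicit-function theorem applied to the collocation equations, with all
partial derivatives obtained by complex-step differentiation (machine
precision, no hand-coded derivatives).

The collocation equations themselves are also exposed (`interval_residual`,
`CollocationProblem.constraint_residuals`) so tests can verify that reduced
solutions satisfy the full-space transcription and that the objective
decomposes exactly into MSE + smoothing parts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial import polynomial as P

from ..data import MeasurementDataset
from .ann import ANNSpec
from .objectives import mse_objective, smoothness_penalty


# --------------------------------------------------------------------------
# Radau IIA nodes and differentiation matrices
# --------------------------------------------------------------------------
@lru_cache(maxsize=None)
def radau_points(K: int) -> tuple[float, ...]:
    """Radau IIA abscissae on (0, 1], right endpoint included."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return (1.0,)
    # roots of d^{K-1}/dx^{K-1} [ x^{K-1} (x-1)^K ]
    poly = P.polymul(P.polypow([0.0, 1.0], K - 1), P.polypow([-1.0, 1.0], K))
    for _ in range(K - 1):
        poly = P.polyder(poly)
    roots = np.sort(np.roots(poly[::-1]).real)
    return tuple(float(r) for r in roots)


@lru_cache(maxsize=None)
def diff_matrix(K: int) -> np.ndarray:
    """Lagrange differentiation matrix D[i, k] = L_k'(c_i) on nodes {0, c_1..c_K}."""
    c = np.array(radau_points(K))
    nodes = np.concatenate([[0.0], c])
    D = np.zeros((K, K + 1))
    for k in range(K + 1):
        e = np.zeros(K + 1)
        e[k] = 1.0
        coef = P.polyfit(nodes, e, K)
        D[:, k] = P.polyval(c, P.polyder(coef))
    return D


# --------------------------------------------------------------------------
# complex-step differentiation
# --------------------------------------------------------------------------
_CS_H = 1e-30


def complex_step_jacobian(f, x: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Jacobian of ``f`` at real ``x`` via batched complex-step.

    ``f`` must accept an array with a leading batch axis, i.e. map shape
    ``(b, n)`` to ``(b, m)``, using only complex-analytic operations.
    """
    x = np.asarray(x, float)
    n = x.size
    blocks = []
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        X = np.repeat(x[None, :].astype(complex), idx.size, axis=0)
        X[np.arange(idx.size), idx] += 1j * _CS_H
        F = np.asarray(f(X))
        blocks.append(F.imag.T / _CS_H)
    return np.concatenate(blocks, axis=1) if blocks else np.empty((0, 0))


# --------------------------------------------------------------------------
# grid
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class CollocationGrid:
    """Finite elements aligned with measurement intervals.

    Each of the ``M - 1`` measurement intervals is split into ``nsub`` equal
    sub-elements carrying ``K`` Radau points each, so every measurement time
    is a grid node (the right endpoint of its interval's last sub-element).
    """

    times: tuple[float, ...]
    K: int = 5
    nsub: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing, >= 2 points")
        if self.K < 1 or self.nsub < 1:
            raise ValueError("K and nsub must be >= 1")

    @classmethod
    def for_data(cls, data: MeasurementDataset, K: int = 5, nsub: int = 2) -> "CollocationGrid":
        """Default estimation grid: 5-point Radau, two sub-elements per
        measurement interval (discretization bias well below measurement
        noise and small enough not to shift noise-free parameter optima)."""
        return cls(tuple(float(t) for t in data.times), K=K, nsub=nsub)

    @property
    def n_intervals(self) -> int:
        return len(self.times) - 1

    @property
    def n_interval_nodes(self) -> int:
        """Unknown nodes per interval (the interval start is inherited)."""
        return self.nsub * self.K

    def local_offsets(self) -> np.ndarray:
        """Node positions within an interval on (0, 1], shape (nsub*K,)."""
        c = np.array(radau_points(self.K))
        return ((np.arange(self.nsub)[:, None] + c[None, :]) / self.nsub).ravel()


# --------------------------------------------------------------------------
# interval residuals (the collocation equality constraints)
# --------------------------------------------------------------------------
def interval_residual(grid, rhs, theta, y0, U, h, mu_pair=None, ann=None,
                      ann_flat=None, ann_at="collocation"):
    """Collocation residuals of one measurement interval, batched.

    Parameters
    ----------
    y0 : array (..., S)
        State at the interval start (inherited from the previous interval).
    U : array (..., nsub*K, S)
        Unknown node states of the interval.
    h : float
        Interval length.
    mu_pair : None or tuple (mu0, mu1) of arrays (...,)
        Time-variant parameter value at the interval's two measurement
        endpoints; linearly interpolated to the collocation nodes (the TVPE
        convention, where the free values live at measurement times).
    ann, ann_flat
        Embedded-network spec and its (possibly batched) flat weights.  With
        ``ann_at="collocation"`` (the embedded default, mirroring a DAE
        formulation where the algebraic network constraint holds at every
        collocation point) the network is evaluated on the state at each
        collocation node; with ``ann_at="nodes"`` it is evaluated at the
        interval end state only and interpolated like a TVPE value (then
        ``mu_pair[0]`` supplies the interval-start value).

    Returns
    -------
    array (..., nsub*K, S) of residuals; zero iff the Radau collocation
    equations hold on every sub-element.
    """
    K, nsub = grid.K, grid.nsub
    D = diff_matrix(K)
    S = U.shape[-1]
    y0 = np.asarray(y0)
    batch = np.broadcast_shapes(U.shape[:-2], y0.shape[:-1])
    U = np.broadcast_to(U, (*batch, *U.shape[-2:]))
    y0 = np.broadcast_to(y0, (*batch, S))
    Usub = U.reshape(*batch, nsub, K, S)
    # start state of each sub-element: y0 for the first, previous end node after
    starts = np.concatenate([y0[..., None, :], Usub[..., :-1, -1, :]], axis=-2)
    X = np.concatenate([starts[..., None, :], Usub], axis=-2)  # (..., nsub, K+1, S)
    dX = np.einsum("ik,...nks->...nis", D, X)  # (..., nsub, K, S)
    hsub = h / nsub

    if ann is not None and ann_at == "collocation":
        flat_b = np.asarray(ann_flat)[..., None, None, :]
        mu = ANNSpec.forward_flat(ann, flat_b, Usub)[..., 0]  # (..., nsub, K)
        f = rhs(Usub, theta, mu)
    elif mu_pair is not None:
        mu0, mu1 = mu_pair
        if ann is not None:
            y_end = U[..., -1, :]
            mu1 = ANNSpec.forward_flat(ann, ann_flat, y_end)[..., 0]
        offs = grid.local_offsets().reshape(nsub, K)
        mu = (
            mu0[..., None, None] * (1.0 - offs)
            + mu1[..., None, None] * offs
        )  # (..., nsub, K)
        f = rhs(Usub, theta, mu)
    else:
        f = rhs(Usub, theta, None)
    res = dX - hsub * f  # batch may come from U, y0, theta, mu or ann weights
    return res.reshape(*res.shape[:-3], nsub * K, S)


def _newton_interval(grid, rhs, theta, y0, h, mu_pair, ann, ann_flat, U0,
                     scale, tol=1e-11, max_iter=25, ann_at="collocation"):
    """Solve the interval collocation equations for the node states."""
    nU = grid.n_interval_nodes * y0.shape[-1]
    S = y0.shape[-1]
    U = np.array(U0, float)

    def res_flat(Uf):
        return interval_residual(
            grid, rhs, theta, y0, Uf.reshape(*Uf.shape[:-1], -1, S),
            h, mu_pair, ann, ann_flat, ann_at
        ).reshape(*Uf.shape[:-1], nU)

    def norm_of(Uv):
        r = interval_residual(grid, rhs, theta, y0, Uv, h, mu_pair, ann,
                              ann_flat, ann_at)
        if not np.all(np.isfinite(r)):
            return r, np.inf
        return r, float(np.max(np.abs(r) / scale))

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        A = None
        r, norm = norm_of(U)
        for it in range(max_iter):
            if norm < tol:
                return U, True
            if not np.isfinite(norm):
                return U, False
            if A is None or it % 3 == 2:
                A = complex_step_jacobian(res_flat, U.ravel())
            try:
                step = np.linalg.solve(A, r.ravel())
            except np.linalg.LinAlgError:
                return U, False
            if not np.all(np.isfinite(step)):
                return U, False
            # damped update: halve the step until the residual stops growing
            alpha = 1.0
            for _ in range(5):
                U_new = (U.ravel() - alpha * step).reshape(U.shape)
                r_new, norm_new = norm_of(U_new)
                if norm_new < norm or norm_new < tol:
                    break
                alpha *= 0.5
            else:
                A = complex_step_jacobian(res_flat, U.ravel())
                continue
            U, r, norm = U_new, r_new, norm_new
    return U, norm < tol


class MarchFailure(RuntimeError):
    """Raised when the collocation equations cannot be solved for a candidate."""


def radau_march(grid, rhs, theta, y0, mu_nodes=None, ann=None, ann_flat=None,
                guess=None, scale=None, return_internal=False,
                ann_at="collocation"):
    """Solve the transcribed dynamics interval-by-interval for one condition.

    This computes the unique state trajectory satisfying all collocation
    equality constraints for the given parameters — the feasibility
    projection of the full-space NLP.  Returns the states at the measurement
    nodes, shape ``(M, S)`` (and optionally all internal node states).

    ``mu_nodes``: time-variant parameter values at the M measurement nodes
    (ignored entries beyond index 0 when ``ann`` is given, in which case
    ``mu_nodes[0]`` seeds the initial node and subsequent node values come
    from the embedded network).
    """
    times = np.asarray(grid.times)
    y0 = np.asarray(y0, float)
    S = y0.size
    M = times.size
    if scale is None:
        scale = np.maximum(np.abs(y0), 1.0)
    out = np.empty((M, S))
    out[0] = y0
    internal = []
    y = y0
    mu_vals = None
    if mu_nodes is not None or ann is not None:
        mu_vals = np.empty(M)
        if ann is not None:
            mu_vals[0] = float(ANNSpec.forward_flat(ann, ann_flat, y0)[..., 0])
        else:
            mu_vals[:] = np.asarray(mu_nodes, float)
    for j in range(M - 1):
        h = times[j + 1] - times[j]
        if guess is not None:
            offs = grid.local_offsets()
            U0 = y[None, :] * (1 - offs[:, None]) + guess[j + 1][None, :] * offs[:, None]
        else:
            U0 = np.repeat(y[None, :], grid.n_interval_nodes, axis=0)
        mu_pair = None
        if mu_vals is not None and not (ann is not None and ann_at == "collocation"):
            mu0 = np.asarray(mu_vals[j])
            mu1 = np.asarray(mu_vals[j + 1]) if ann is None else np.asarray(0.0)
            mu_pair = (mu0, mu1)
        U, ok = _newton_interval(grid, rhs, theta, y, h, mu_pair, ann, ann_flat,
                                 U0, scale, ann_at=ann_at)
        if not ok:
            raise MarchFailure(f"collocation solve failed on interval {j}")
        y = U[-1]
        out[j + 1] = y
        if ann is not None:
            mu_vals[j + 1] = float(ANNSpec.forward_flat(ann, ann_flat, y)[..., 0])
        internal.append(U)
    if return_internal:
        return out, internal, mu_vals
    return out


def collocation_simulate(grid, rhs, y0, theta=None, mu_nodes=None, ann=None,
                         ann_flat=None, guess=None):
    """Feasibility 'simulation' through the collocation transcription.

    Thin wrapper over :func:`radau_march` used to verify transcription
    fidelity against an adaptive integrator at fixed parameters.
    """
    return radau_march(grid, rhs, theta or {}, y0, mu_nodes=mu_nodes, ann=ann,
                       ann_flat=ann_flat, guess=guess)


# --------------------------------------------------------------------------
# parameter maps: decision vector <-> (theta, mu-nodes | ANN weights)
# --------------------------------------------------------------------------
@dataclass
class ParamMap:
    """Layout of the reduced decision vector.

    ``tiv_names`` are time-invariant parameters (entered in natural units,
    non-negative unless overridden); ``n_tv_conditions > 0`` adds one free
    time-variant value per (condition, measurement time); ``ann`` embeds a
    network whose flat weights join the vector, boxed to [-1, 1] when the
    spec is flagged ``bounded``.
    """

    tiv_names: tuple[str, ...]
    n_times: int = 0
    n_tv_conditions: int = 0
    ann: ANNSpec | None = None
    tiv_lo: np.ndarray | None = None
    tiv_hi: np.ndarray | None = None
    tv_nonneg: bool = False
    #: where an embedded network constrains the time-variant parameter:
    #: at every collocation point (DAE convention) or at measurement nodes
    #: only (with linear interpolation inside an interval)
    ann_at: str = "collocation"

    def __post_init__(self) -> None:
        p = len(self.tiv_names)
        if self.tiv_lo is None:
            self.tiv_lo = np.zeros(p)
        if self.tiv_hi is None:
            self.tiv_hi = np.full(p, np.inf)
        self.tiv_lo = np.asarray(self.tiv_lo, float)
        self.tiv_hi = np.asarray(self.tiv_hi, float)

    @property
    def n_tiv(self) -> int:
        return len(self.tiv_names)

    @property
    def n_tv(self) -> int:
        return self.n_tv_conditions * self.n_times

    @property
    def n_ann(self) -> int:
        return self.ann.n_params if self.ann is not None else 0

    @property
    def n_params(self) -> int:
        return self.n_tiv + self.n_tv + self.n_ann

    def split(self, p):
        """Split a (possibly batched) decision vector into its components."""
        tiv = {name: p[..., i] for i, name in enumerate(self.tiv_names)}
        i = self.n_tiv
        mu = None
        if self.n_tv:
            mu = p[..., i : i + self.n_tv].reshape(
                *p.shape[:-1], self.n_tv_conditions, self.n_times
            )
            i += self.n_tv
        ann_flat = p[..., i:] if self.ann is not None else None
        return tiv, mu, ann_flat

    def join(self, tiv: dict, mu=None, ann_flat=None) -> np.ndarray:
        parts = [np.array([tiv[n] for n in self.tiv_names], float)]
        if self.n_tv:
            parts.append(np.asarray(mu, float).ravel())
        if self.ann is not None:
            parts.append(np.asarray(ann_flat, float).ravel())
        return np.concatenate(parts)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = [self.tiv_lo]
        hi = [self.tiv_hi]
        if self.n_tv:
            lo.append(np.full(self.n_tv, 0.0 if self.tv_nonneg else -np.inf))
            hi.append(np.full(self.n_tv, np.inf))
        if self.ann is not None:
            b = 1.0 if self.ann.bounded else np.inf
            lo.append(np.full(self.n_ann, -b))
            hi.append(np.full(self.n_ann, b))
        return np.concatenate(lo), np.concatenate(hi)


# --------------------------------------------------------------------------
# the transcribed estimation problem (reduced space)
# --------------------------------------------------------------------------
class CollocationProblem:
    """A transcribed dynamic estimation problem over a measurement dataset.

    Parameters
    ----------
    rhs : callable ``rhs(y, theta, mu) -> dy/dt``
        Model right-hand side; must broadcast over leading axes and be
        complex-analytic.  ``y`` has the dataset's species on the last axis;
        ``mu`` is the interpolated time-variant parameter (or None).
    data : MeasurementDataset
    pmap : ParamMap
    w_m, w_s : float
        Weights of the MSE and smoothing terms.  The smoothing term only
        applies when the map carries free time-variant parameters.
    species_scale : array or None
        Per-species normalisation of the MSE (defaults to the per-species
        maxima of the training data).
    """

    #: one-sided penalty restoring the full-space state bounds y >= 0 in
    #: the reduced formulation: kappa * smooth_max(-y/scale, 0); smooth
    #: width eps keeps the residual complex-analytic
    NONNEG_KAPPA = 10.0
    NONNEG_EPS = 1e-6

    def __init__(self, rhs, data: MeasurementDataset, pmap: ParamMap,
                 w_m: float = 1.0, w_s: float = 0.0,
                 grid: CollocationGrid | None = None,
                 species_scale=None, state_nonneg: bool = True):
        self.state_nonneg = state_nonneg
        self.rhs = rhs
        self.data = data
        self.pmap = pmap
        self.w_m = float(w_m)
        self.w_s = float(w_s)
        self.grid = grid or CollocationGrid.for_data(data)
        if pmap.n_tv and pmap.n_times != data.n_times:
            raise ValueError("time-variant parameter grid must match the data grid")
        self.species_scale = (
            np.asarray(species_scale, float)
            if species_scale is not None
            else data.species_scale()
        )
        self._n_meas_res = data.n_conditions * data.n_times * len(self.species_scale)
        self._cache_key: bytes | None = None
        self._cache_val = None

    #: residual magnitude reported when the collocation equations cannot be
    #: solved at a candidate point (the solver then rejects the step)
    PENALTY = 1e3

    @property
    def n_residuals(self) -> int:
        n = self._n_meas_res
        if self.pmap.n_tv and self.w_s > 0:
            n += self.data.n_conditions * (self.data.n_times - 2)
        if self.state_nonneg:
            n += self._n_meas_res
        return n

    def _nonneg_residuals(self, pred) -> np.ndarray:
        u = pred / self.species_scale
        return (self.NONNEG_KAPPA * 0.5
                * (np.sqrt(u * u + self.NONNEG_EPS**2) - u)).ravel()

    # -- forward evaluation -------------------------------------------------
    def _theta_b(self, tiv: dict) -> dict:
        # broadcast scalar parameters against (nsub, K) node axes
        return {k: np.asarray(v)[..., None, None] for k, v in tiv.items()}

    def predict(self, p, return_details=False):
        """States at measurement nodes for decision vector ``p``: (C, M, S)."""
        p = np.asarray(p, float)
        key = p.tobytes()
        if key == self._cache_key:
            out, details = self._cache_val
            return (out, details) if return_details else out
        tiv, mu, ann_flat = self.pmap.split(p)
        theta = self._theta_b(tiv)
        C, M = self.data.n_conditions, self.data.n_times
        S = len(self.species_scale)
        out = np.empty((C, M, S))
        details = []
        for c in range(C):
            mu_c = mu[c] if mu is not None else None
            guess = self.data.observations[c]
            y_nodes, internal, mu_vals = radau_march(
                self.grid, self.rhs, theta, self.data.conditions[c],
                mu_nodes=mu_c, ann=self.pmap.ann, ann_flat=ann_flat,
                guess=guess, scale=self.species_scale, return_internal=True,
                ann_at=self.pmap.ann_at,
            )
            out[c] = y_nodes
            details.append((internal, mu_vals))
        self._cache_key, self._cache_val = key, (out, details)
        if return_details:
            return out, details
        return out

    # -- least-squares residual view -----------------------------------------
    def residuals(self, p) -> np.ndarray:
        """Stacked weighted residuals; their sum of squares equals
        ``w_m * MSE + w_s * SM`` exactly.  When the collocation equations
        cannot be solved at ``p`` a large constant penalty vector is
        returned so trust-region solvers back away from the point."""
        try:
            pred = self.predict(p)
        except MarchFailure:
            return np.full(self.n_residuals, self.PENALTY)
        C, M = self.data.n_conditions, self.data.n_times
        S = len(self.species_scale)
        r_meas = (pred - self.data.observations) / self.species_scale
        r_meas = r_meas.ravel() * np.sqrt(self.w_m / (C * M * S))
        parts = [r_meas]
        tiv, mu, _ = self.pmap.split(np.asarray(p, float))
        if self.pmap.n_tv and self.w_s > 0:
            d2 = mu[:, 2:] - 2.0 * mu[:, 1:-1] + mu[:, :-2]
            parts.append(d2.ravel() * np.sqrt(self.w_s / (C * M)))
        if self.state_nonneg:
            parts.append(self._nonneg_residuals(pred))
        return np.concatenate(parts)

    def objective(self, p) -> float:
        r = self.residuals(p)
        return float(r @ r)

    def objective_parts(self, p) -> dict:
        pred = self.predict(p)
        tiv, mu, _ = self.pmap.split(np.asarray(p, float))
        mse = float(mse_objective(pred, self.data.observations, self.species_scale))
        sm = float(smoothness_penalty(mu)) if self.pmap.n_tv else 0.0
        return {"mse": mse, "smoothing": sm, "total": self.w_m * mse + self.w_s * sm}

    # -- exact Jacobian via implicit-function theorem -------------------------
    def jacobian(self, p) -> np.ndarray:
        p = np.asarray(p, float)
        tiv, mu, ann_flat = self.pmap.split(p)
        theta = self._theta_b(tiv)
        C, M = self.data.n_conditions, self.data.n_times
        S = len(self.species_scale)
        nP = self.pmap.n_params
        nU = self.grid.n_interval_nodes * S
        times = np.asarray(self.grid.times)
        dpred = np.zeros((C, M, S, nP))
        for c in range(C):
            mu_c = mu[c] if mu is not None else None
            y_nodes, internal, mu_vals = radau_march(
                self.grid, self.rhs, theta, self.data.conditions[c],
                mu_nodes=mu_c, ann=self.pmap.ann, ann_flat=ann_flat,
                guess=self.data.observations[c],
                scale=self.species_scale, return_internal=True,
                ann_at=self.pmap.ann_at,
            )
            G = np.zeros((S, nP))  # d y(t_j) / dp, propagated forward
            for j in range(M - 1):
                h = times[j + 1] - times[j]
                U = internal[j]
                y0 = y_nodes[j]

                def res_U(Uf):
                    return self._interval_res_p(
                        p, c, j, y0, Uf.reshape(*Uf.shape[:-1], -1, S), h, mu_vals
                    ).reshape(*Uf.shape[:-1], nU)

                def res_p(pf):
                    return self._interval_res_p(
                        pf, c, j, y0, U, h, mu_vals
                    ).reshape(*pf.shape[:-1], nU)

                def res_y0(y0f):
                    return self._interval_res_p(
                        p, c, j, y0f, U, h, mu_vals
                    ).reshape(*y0f.shape[:-1], nU)

                A = complex_step_jacobian(res_U, U.ravel())
                B = complex_step_jacobian(res_p, p)
                Cm = complex_step_jacobian(res_y0, y0)
                dU = -np.linalg.solve(A, B + Cm @ G)
                G = dU[-S:, :]
                dpred[c, j + 1] = G
        return dpred

    def _interval_res_p(self, p, c, j, y0, U, h, mu_vals):
        """Interval residual as a joint function of (p, y0, U); batched."""
        p = np.asarray(p)
        tiv, mu, ann_flat = self.pmap.split(p)
        theta = self._theta_b(tiv)
        mu_pair = None
        if self.pmap.ann is not None:
            if self.pmap.ann_at == "nodes":
                # mu0 at the interval start: network on the start state (the
                # fixed condition at j=0, the inherited y0 after)
                y_start = self.data.conditions[c] if j == 0 else np.asarray(y0)
                mu0 = ANNSpec.forward_flat(self.pmap.ann, ann_flat,
                                           y_start)[..., 0]
                mu_pair = (mu0, np.asarray(0.0))
        elif mu is not None:
            mu_pair = (mu[..., c, j], mu[..., c, j + 1])
        elif mu_vals is not None:
            mu_pair = (np.asarray(mu_vals[j]), np.asarray(mu_vals[j + 1]))
        return interval_residual(
            self.grid, self.rhs, theta, np.asarray(y0), np.asarray(U), h,
            mu_pair, self.pmap.ann, ann_flat, self.pmap.ann_at,
        )

    def residual_jacobian(self, p) -> np.ndarray:
        """Jacobian of :meth:`residuals` with respect to ``p``.  At penalty
        points (unsolvable collocation equations) a zero Jacobian is
        returned; trust-region solvers never accept such points anyway."""
        p = np.asarray(p, float)
        C, M = self.data.n_conditions, self.data.n_times
        S = len(self.species_scale)
        try:
            dpred = self.jacobian(p)
        except MarchFailure:
            return np.zeros((self.n_residuals, p.size))
        w = np.sqrt(self.w_m / (C * M * S))
        J_meas = (dpred / self.species_scale[None, None, :, None] * w).reshape(-1, p.size)
        blocks = [J_meas]
        if self.pmap.n_tv and self.w_s > 0:
            nsm = C * (M - 2)
            J_sm = np.zeros((nsm, p.size))
            ws = np.sqrt(self.w_s / (C * M))
            row = 0
            for c in range(C):
                base = self.pmap.n_tiv + c * M
                for j in range(M - 2):
                    J_sm[row, base + j] = ws
                    J_sm[row, base + j + 1] = -2.0 * ws
                    J_sm[row, base + j + 2] = ws
                    row += 1
            blocks.append(J_sm)
        if self.state_nonneg:
            pred = self.predict(p)
            u = pred / self.species_scale
            d = (self.NONNEG_KAPPA * 0.5
                 * (u / np.sqrt(u * u + self.NONNEG_EPS**2) - 1.0))
            J_neg = (dpred / self.species_scale[None, None, :, None]
                     * d[..., None]).reshape(-1, p.size)
            blocks.append(J_neg)
        return np.concatenate(blocks, axis=0)

    # -- full-space constraint view (for verification tests) ------------------
    def constraint_residuals(self, p) -> np.ndarray:
        """All collocation equality-constraint residuals at the reduced
        solution implied by ``p`` (should vanish to solver tolerance)."""
        pred, details = self.predict(np.asarray(p, float), return_details=True)
        tiv, mu, ann_flat = self.pmap.split(np.asarray(p, float))
        theta = self._theta_b(tiv)
        times = np.asarray(self.grid.times)
        res = []
        for c in range(self.data.n_conditions):
            internal, mu_vals = details[c]
            for j in range(self.data.n_times - 1):
                mu_pair = None
                if mu_vals is not None and not (
                    self.pmap.ann is not None and self.pmap.ann_at == "collocation"
                ):
                    mu_pair = (np.asarray(mu_vals[j]), np.asarray(mu_vals[j + 1]))
                    if self.pmap.ann is not None:
                        mu_pair = (mu_pair[0], np.asarray(0.0))
                r = interval_residual(
                    self.grid, self.rhs, theta, pred[c, j], internal[j],
                    times[j + 1] - times[j], mu_pair, self.pmap.ann, ann_flat,
                    self.pmap.ann_at,
                )
                res.append(np.ravel(r))
        return np.concatenate(res)
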
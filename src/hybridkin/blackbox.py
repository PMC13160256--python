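"""Pure-ML baseline: a direct map from initial condition and time to state.

The network predicts all four observable concentrations at time ``t`` from
the initial observable state, ``(Xt0, Cg0, Cm0, Cc0, t) -> (Xt, Cg, Cm,
Cc)``.  Inputs and outputs are Z-score normalised; the architecture is
chosen by 5-fold cross-validated grid search over activation, depth, width
and L2 strength.  By construction the model has no mechanism to react to
fed-batch substrate spikes — its inputs are initial conditions only — which
is exactly the structural weakness the extrapolative comparison probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .data import OBS_SPECIES, MeasurementDataset, StateTrajectory
from .dynopt.ann import ANNSpec

#: default CV grid: activation x (layers, nodes) x L2 strength
DEFAULT_BLACKBOX_GRID = [
    {"hidden": h, "activation": a, "alpha": al}
    for a in ("tanh", "relu")
    for h in ((8,), (16,), (8, 8))
    for al in (1e-4, 1e-3)
]


@dataclass
class ZScaler:
    """Per-feature Z-score normalisation; constant features use scale 1."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, table: np.ndarray) -> "ZScaler":
        table = np.asarray(table, float)
        mean = table.mean(axis=0)
        std = table.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=mean, std=std)

    def apply(self, table: np.ndarray) -> np.ndarray:
        return (np.asarray(table, float) - self.mean) / self.std

    def invert(self, table: np.ndarray) -> np.ndarray:
        return np.asarray(table, float) * self.std + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScaler":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


def fit_scaler(table: np.ndarray) -> ZScaler:
    """Functional alias for :meth:`ZScaler.fit`."""
    return ZScaler.fit(table)


def polish_output_layer(mlp, X, y) -> None:
    """Refit the (identity-activation) output layer by exact least squares.

    Given the hidden activations, the output layer is a linear model; the
    closed-form solve removes the small plateau residue that L-BFGS leaves
    behind (its relative-decrease stopping rule bites before the optimum on
    nearly-flat basins).  Regularisation is dropped for this final polish.
    """
    h = np.asarray(X, float)
    for W, b in zip(mlp.coefs_[:-1], mlp.intercepts_[:-1]):
        z = h @ W + b
        h = np.tanh(z) if mlp.activation == "tanh" else np.maximum(z, 0.0)
    A = np.column_stack([h, np.ones(h.shape[0])])
    sol, *_ = np.linalg.lstsq(A, np.atleast_2d(np.asarray(y, float).T).T,
                              rcond=None)
    mlp.coefs_[-1] = sol[:-1].reshape(mlp.coefs_[-1].shape)
    mlp.intercepts_[-1] = np.atleast_1d(sol[-1])


@dataclass
class BlackboxModel:
    """Fitted surrogate: network spec plus the input/output Z-scalers."""

    ann: ANNSpec
    x_scaler: ZScaler
    y_scaler: ZScaler
    cv_record: list = field(default_factory=list)
    seed: int | None = None

    def predict(self, init, times) -> StateTrajectory:
        """Vectorised prediction of the observable state at ``times``.

        ``init`` is the initial observable state (Xt, Cg, Cc, Cm); spikes
        applied later in the run are invisible to this model.
        """
        init = np.asarray(init, float)
        times = np.atleast_1d(np.asarray(times, float))
        X = np.column_stack([np.tile(init, (times.size, 1)), times])
        ys = self.ann.forward(self.x_scaler.apply(X))
        states = self.y_scaler.invert(ys)
        return StateTrajectory(times, states, OBS_SPECIES, {"model": "blackbox"})

    def to_dict(self) -> dict:
        return {
            "ann": self.ann.to_dict(),
            "x_scaler": self.x_scaler.to_dict(),
            "y_scaler": self.y_scaler.to_dict(),
            "cv_record": self.cv_record,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlackboxModel":
        return cls(
            ann=ANNSpec.from_dict(d["ann"]),
            x_scaler=ZScaler.from_dict(d["x_scaler"]),
            y_scaler=ZScaler.from_dict(d["y_scaler"]),
            cv_record=d.get("cv_record", []),
            seed=d.get("seed"),
        )


def _design_matrices(data: MeasurementDataset) -> tuple[np.ndarray, np.ndarray]:
    rows_x, rows_y = [], []
    for c in range(data.n_conditions):
        init = data.conditions[c]
        for j in range(data.n_times):
            rows_x.append(np.append(init, data.times[j]))
            rows_y.append(data.observations[c, j])
    return np.asarray(rows_x), np.asarray(rows_y)


def train_blackbox(
    data: MeasurementDataset,
    arch_grid=None,
    k_folds: int = 5,
    seed: int = 0,
) -> BlackboxModel:
    """Cross-validated grid-search training of the black-box surrogate.

    Rows are pooled over conditions; scalers are fitted on the respective
    training split inside each fold and on all rows for the final refit.
    """
    arch_grid = arch_grid or DEFAULT_BLACKBOX_GRID
    X, Y = _design_matrices(data)
    if X.shape[0] < 2 * k_folds:
        raise ValueError(
            f"need at least {2 * k_folds} rows for {k_folds}-fold CV, got {X.shape[0]}"
        )

    def make(cell, rs):
        return MLPRegressor(
            hidden_layer_sizes=tuple(cell["hidden"]),
            activation=cell.get("activation", "tanh"),
            alpha=cell.get("alpha", 1e-4),
            solver="lbfgs",
            max_iter=4000,
            tol=1e-9,
            random_state=rs,
        )

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    record, scores = [], []
    for ci, cell in enumerate(arch_grid):
        fold_mse = []
        for fi, (tr, va) in enumerate(kf.split(X)):
            xs, ys = ZScaler.fit(X[tr]), ZScaler.fit(Y[tr])
            m = make(cell, seed + fi)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(xs.apply(X[tr]), ys.apply(Y[tr]))
            polish_output_layer(m, xs.apply(X[tr]), ys.apply(Y[tr]))
            pred = ys.invert(m.predict(xs.apply(X[va])))
            mse = float(np.mean(((pred - Y[va]) / ys.std) ** 2))
            record.append({
                "cell": ci, "fold": fi, "val_mse": mse,
                "hidden": list(cell["hidden"]),
                "activation": cell.get("activation", "tanh"),
                "alpha": cell.get("alpha", 1e-4),
            })
            fold_mse.append(mse)
        scores.append(float(np.mean(fold_mse)))
    best = arch_grid[int(np.argmin(scores))]

    xs, ys = ZScaler.fit(X), ZScaler.fit(Y)
    final = make(best, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(xs.apply(X), ys.apply(Y))
    polish_output_layer(final, xs.apply(X), ys.apply(Y))
    ann = ANNSpec.from_sklearn(
        final,
        input_names=("Xt0", "Cg0", "Cc0", "Cm0", "t"),
        output_activation="identity",
    )
    return BlackboxModel(ann=ann, x_scaler=xs, y_scaler=ys, cv_record=record,
                         seed=seed)


def predict_blackbox(model: BlackboxModel, init, times) -> StateTrajectory:
    """Functional alias for :meth:`BlackboxModel.predict`."""
    return model.predict(init, times)
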
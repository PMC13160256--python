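"""Feed-forward network algebra for embedded and standalone use.

An :class:`ANNSpec` is a plain dense multilayer perceptron whose forward
pass is written in broadcast-friendly numpy so the same code path serves
three roles: (i) a numeric predictor, (ii) a smooth algebraic expression
inside a collocation NLP (evaluated on complex-perturbed decision variables
for exact complex-step derivatives), and (iii) the subject of exact-gradient
Integrated-Gradients attribution.

Inputs are affinely scaled inside the forward pass
(``x_scaled = (x - offset) * scale``); for networks embedded in an NLP with
weights boxed to [-1, 1] the scaling maps each training input to [0, 1] so
tanh units do not saturate on mM-sized concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_HIDDEN_ACTS = ("tanh", "relu", "logistic")
_OUTPUT_ACTS = ("identity", "tanh", "sigmoid", "softplus")


def _act(name: str, z):
    if name == "tanh":
        return np.tanh(z)
    if name == "relu":
        return np.maximum(z, 0.0) if not np.iscomplexobj(z) else np.where(z.real > 0, z, 0.0)
    if name == "logistic" or name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "identity":
        return z
    if name == "softplus":
        return np.log1p(np.exp(z))
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, z):
    if name == "tanh":
        return 1.0 - np.tanh(z) ** 2
    if name == "relu":
        return (z > 0).astype(float)
    if name in ("logistic", "sigmoid"):
        s = 1.0 / (1.0 + np.exp(-z))
        return s * (1.0 - s)
    if name == "identity":
        return np.ones_like(z)
    if name == "softplus":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class ANNSpec:
    """Architecture + flattened weights of a dense feed-forward network.

    ``weights[l]`` has shape ``(fan_in, fan_out)`` and ``biases[l]`` shape
    ``(fan_out,)``.  When ``bounded`` is set the weights and biases are
    box-constrained to [-1, 1] (the embedded-network convention).
    """

    n_inputs: int
    hidden: tuple[int, ...] = (4,)
    hidden_activation: str = "tanh"
    output_activation: str = "identity"
    n_outputs: int = 1
    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)
    input_offset: np.ndarray | None = None
    input_scale: np.ndarray | None = None
    bounded: bool = False
    input_names: tuple[str, ...] | None = None
    #: multiplier applied after the output activation; with a bounded output
    #: activation it sets the physical range of the network's prediction
    output_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.hidden_activation not in _HIDDEN_ACTS:
            raise ValueError(f"hidden activation must be one of {_HIDDEN_ACTS}")
        if self.output_activation not in _OUTPUT_ACTS:
            raise ValueError(f"output activation must be one of {_OUTPUT_ACTS}")
        if self.input_offset is None:
            self.input_offset = np.zeros(self.n_inputs)
        if self.input_scale is None:
            self.input_scale = np.ones(self.n_inputs)
        self.input_offset = np.asarray(self.input_offset, float)
        self.input_scale = np.asarray(self.input_scale, float)
        if not self.weights:
            shapes = self.layer_shapes()
            self.weights = [np.zeros(s) for s in shapes]
            self.biases = [np.zeros(s[1]) for s in shapes]
        for (w, b), s in zip(zip(self.weights, self.biases), self.layer_shapes()):
            if np.shape(w) != s or np.shape(b) != (s[1],):
                raise ValueError("weight/bias shapes inconsistent with architecture")

    # ---- shapes and flat parameter vector -------------------------------
    def layer_shapes(self) -> list[tuple[int, int]]:
        sizes = [self.n_inputs, *self.hidden, self.n_outputs]
        return [(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]

    @property
    def n_params(self) -> int:
        return sum(a * b + b for a, b in self.layer_shapes())

    def get_flat(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(np.ravel(w))
            parts.append(np.ravel(b))
        return np.concatenate(parts) if parts else np.empty(0)

    def set_flat(self, flat: np.ndarray) -> "ANNSpec":
        flat = np.asarray(flat)
        if flat.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {flat.size}")
        i = 0
        ws, bs = [], []
        for a, b in self.layer_shapes():
            ws.append(flat[i : i + a * b].reshape(a, b))
            i += a * b
            bs.append(flat[i : i + b])
            i += b
        self.weights, self.biases = ws, bs
        return self

    @staticmethod
    def forward_flat(spec: "ANNSpec", flat, x):
        """Forward pass with externally supplied (possibly complex) weights.

        ``flat`` may carry a leading batch axis congruent with ``x``; used by
        the NLP path where the weights are decision variables.
        """
        xs = (x - spec.input_offset) * spec.input_scale
        i = 0
        h = xs
        shapes = spec.layer_shapes()
        for li, (a, b) in enumerate(shapes):
            W = flat[..., i : i + a * b].reshape(*flat.shape[:-1], a, b)
            i += a * b
            bias = flat[..., i : i + b]
            i += b
            z = np.einsum("...i,...io->...o", h, W) + bias
            act = spec.hidden_activation if li < len(shapes) - 1 else spec.output_activation
            h = _act(act, z)
        return h * spec.output_scale

    # ---- numeric paths ---------------------------------------------------
    def forward(self, x) -> np.ndarray:
        """Evaluate the network at raw (unscaled) inputs, batched over leading axes."""
        x = np.asarray(x)
        if x.shape[-1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {x.shape[-1]}")
        h = (x - self.input_offset) * self.input_scale
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            act = self.hidden_activation if li < n_layers - 1 else self.output_activation
            h = _act(act, z)
        return h * self.output_scale

    def input_gradient(self, x) -> np.ndarray:
        """Exact Jacobian d output / d raw input, shape (..., n_outputs, n_inputs)."""
        x = np.asarray(x, float)
        h = (x - self.input_offset) * self.input_scale
        pre = []
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            pre.append(z)
            act = self.hidden_activation if li < n_layers - 1 else self.output_activation
            h = _act(act, z)
        # reverse accumulation of the Jacobian
        jac = np.broadcast_to(
            np.eye(self.n_outputs), (*x.shape[:-1], self.n_outputs, self.n_outputs)
        ).copy()
        for li in range(n_layers - 1, -1, -1):
            act = self.hidden_activation if li < n_layers - 1 else self.output_activation
            d = _act_deriv(act, pre[li])  # (..., fan_out)
            jac = (jac * d[..., None, :]) @ self.weights[li].T
        return jac * self.input_scale * self.output_scale

    # ---- initialisation and serialisation --------------------------------
    def randomize(self, rng: np.random.Generator, scale: float = 0.5) -> "ANNSpec":
        """Seeded uniform initialisation in [-scale, scale] (within the box)."""
        self.set_flat(rng.uniform(-scale, scale, self.n_params))
        return self

    def init_flat(self, rng: np.random.Generator, hidden_scale: float = 0.5,
                  output_scale: float = 0.1) -> np.ndarray:
        """Random flat weights with a deliberately small output layer, so an
        embedded network starts with modest output magnitudes (keeping the
        initial dynamics integrable)."""
        flat = rng.uniform(-hidden_scale, hidden_scale, self.n_params)
        a, b = self.layer_shapes()[-1]
        n_out_block = a * b + b
        flat[-n_out_block:] = rng.uniform(-output_scale, output_scale, n_out_block)
        return flat

    def with_input_scaling(self, lo: np.ndarray, hi: np.ndarray) -> "ANNSpec":
        """Freeze an affine map of each input from [lo, hi] to [0, 1]."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        span = np.where(hi > lo, hi - lo, 1.0)
        self.input_offset = lo
        self.input_scale = 1.0 / span
        return self

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "hidden": list(self.hidden),
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "n_outputs": self.n_outputs,
            "flat": self.get_flat().tolist(),
            "input_offset": self.input_offset.tolist(),
            "input_scale": self.input_scale.tolist(),
            "bounded": self.bounded,
            "input_names": list(self.input_names) if self.input_names else None,
            "output_scale": self.output_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANNSpec":
        spec = cls(
            n_inputs=d["n_inputs"],
            hidden=tuple(d["hidden"]),
            hidden_activation=d["hidden_activation"],
            output_activation=d["output_activation"],
            n_outputs=d["n_outputs"],
            input_offset=np.asarray(d["input_offset"]),
            input_scale=np.asarray(d["input_scale"]),
            bounded=d.get("bounded", False),
            input_names=tuple(d["input_names"]) if d.get("input_names") else None,
            output_scale=d.get("output_scale", 1.0),
        )
        spec.set_flat(np.asarray(d["flat"]))
        return spec

    @classmethod
    def from_sklearn(
        cls,
        mlp,
        input_offset=None,
        input_scale=None,
        output_activation: str = "identity",
        input_names=None,
    ) -> "ANNSpec":
        """Wrap a fitted sklearn MLPRegressor as an ANNSpec.

        Note sklearn applies no input scaling itself; pass the scaling that
        was applied to its training matrix so ``forward`` accepts raw inputs.
        """
        weights = [np.array(w) for w in mlp.coefs_]
        biases = [np.array(b) for b in mlp.intercepts_]
        n_in = weights[0].shape[0]
        n_out = weights[-1].shape[1]
        spec = cls(
            n_inputs=n_in,
            hidden=tuple(w.shape[1] for w in weights[:-1]),
            hidden_activation=mlp.activation,
            output_activation=output_activation,
            n_outputs=n_out,
            weights=weights,
            biases=biases,
            input_offset=input_offset,
            input_scale=input_scale,
            input_names=tuple(input_names) if input_names else None,
        )
        return spec


def ann_forward(spec: ANNSpec, inputs) -> np.ndarray:
    """Functional alias for :meth:`ANNSpec.forward`."""
    return spec.forward(inputs)
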
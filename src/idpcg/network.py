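"""The 6-12-5 feedforward network: forward pass, scaling, fixed point, I/O.

Inference is a static single pass — scaled features through a hidden layer
of 12 units and an output layer of 5 units, both using the (truncated)
inverse-tanh activation.  An optional "settle" mode instead treats the
trained weights as ID-network synapses and integrates the neuron dynamics
until the outputs stop moving; both readings of a "delayed weighted sum"
are thereby available, with the static pass as the default.

Fixed-point deployment is emulated in software: weights, biases and every
intermediate are rounded to a signed Qm.n format with saturating
arithmetic, matching what hard-coded weights on an FPGA would compute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .activation import ActivationSpec
from .synth import CLASS_NAMES

__all__ = [
    "FeatureScaler",
    "MLPModel",
    "FixedPointFormat",
    "ModelFormatError",
    "forward",
    "forward_settled",
    "classify",
    "quantize_model",
    "forward_fixed",
    "save_model",
    "load_model",
    "mse",
    "regression_r",
]

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    pass


@dataclass
class FeatureScaler:
    """Per-feature affine map onto [-1, 1] from training min/max."""

    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        return self

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def _span(self) -> np.ndarray:
        return self.maxs - self.mins

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map to [-1, 1]; out-of-range (test-time) values are clamped.

        A feature that was constant during fitting carries no information
        and maps to 0 regardless of its value.
        """
        if not self.fitted:
            raise ValueError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        span = self._span()
        safe = np.where(span > 0, span, 1.0)
        z = 2.0 * (X - self.mins) / safe - 1.0
        z = np.where(span > 0, z, 0.0)
        return np.clip(z, -1.0, 1.0)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("scaler is not fitted")
        Z = np.asarray(Z, dtype=float)
        span = self._span()
        return np.where(span > 0, (Z + 1.0) / 2.0 * span + self.mins, self.mins)


@dataclass
class MLPModel:
    """Weights and metadata of the feedforward heart-sound classifier."""

    W_hidden: np.ndarray  # (n_hidden, n_in)
    b_hidden: np.ndarray
    W_out: np.ndarray  # (n_out, n_hidden)
    b_out: np.ndarray
    act: ActivationSpec = field(default_factory=ActivationSpec)
    scaler: FeatureScaler | None = None
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.W_hidden = np.asarray(self.W_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        nh, ni = self.W_hidden.shape
        no = self.W_out.shape[0]
        if self.b_hidden.shape != (nh,) or self.W_out.shape != (no, nh) or self.b_out.shape != (no,):
            raise ValueError("inconsistent layer shapes")
        for arr in (self.W_hidden, self.b_hidden, self.W_out, self.b_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weight")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.W_hidden.shape[1], self.W_hidden.shape[0], self.W_out.shape[0])


def forward(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Static forward pass; accepts a single vector or an (n, 6) matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    hidden = np.asarray(model.act(X @ model.W_hidden.T + model.b_hidden))
    scores = np.asarray(model.act(hidden @ model.W_out.T + model.b_out))
    return scores[0] if np.asarray(features).ndim == 1 else scores


def forward_settled(
    model: MLPModel,
    features: np.ndarray,
    params=None,
    dt: float | None = None,
    tol: float = 1e-6,
    max_steps: int = 200000,
) -> np.ndarray:
    """Alternative "settled" inference: integrate the ID dynamics layer-wise.

    Each layer's units are driven by the constant weighted-sum input
    ``W f + b`` and their outputs evolve under the ID equations until
    ``max |dx/dt| < tol``.  With K = 0 the settled output equals the static
    activation of the input up to the tolerance; exposed for completeness.
    """
    from .dynamics import IDParams

    p = params or IDParams()
    x1 = np.asarray(features, dtype=float)
    single = x1.ndim == 1
    X = np.atleast_2d(x1)
    dt = dt if dt is not None else p.tau_x / 20.0
    lim = 1.0 - model.act.clamp_eps
    act = model.act

    def settle(drive: np.ndarray) -> np.ndarray:
        u = np.zeros_like(drive)
        x = np.zeros_like(drive)
        for _ in range(max_steps):
            du = (drive - u) / p.tau
            dx = (u - np.asarray(act.g(x))) / p.tau_x
            u = u + dt * du
            x = np.clip(x + dt * dx, -lim, lim)
            if np.max(np.abs(dx)) < tol and np.max(np.abs(du)) < tol:
                break
        return x

    hidden = settle(X @ model.W_hidden.T + model.b_hidden)
    out = settle(hidden @ model.W_out.T + model.b_out)
    return out[0] if single else out


def classify(model: MLPModel, features: np.ndarray) -> "int | np.ndarray":
    """Argmax class index; exact ties break toward the lowest index."""
    scores = forward(model, features)
    if scores.ndim == 1:
        return int(np.argmax(scores))
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# fixed-point emulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPointFormat:
    """Signed fixed-point format: ``word_bits`` total, ``frac_bits`` fractional."""

    word_bits: int = 32
    frac_bits: int = 24
    signed: bool = True

    def __post_init__(self):
        if not (0 < self.frac_bits < self.word_bits <= 32):
            raise ValueError("requires 0 < frac_bits < word_bits <= 32")

    @property
    def scale(self) -> float:
        return float(2**self.frac_bits)

    @property
    def max_val(self) -> float:
        ibits = self.word_bits - self.frac_bits - (1 if self.signed else 0)
        return float(2**ibits) - 1.0 / self.scale

    @property
    def min_val(self) -> float:
        if not self.signed:
            return 0.0
        return -float(2 ** (self.word_bits - self.frac_bits - 1))

    def quantize(self, v, saturate: bool = True):
        arr = np.asarray(v, dtype=float)
        q = np.round(arr * self.scale) / self.scale
        if saturate:
            q = np.clip(q, self.min_val, self.max_val)
        elif np.any((q > self.max_val) | (q < self.min_val)):
            loc = np.unravel_index(
                int(np.argmax((q > self.max_val) | (q < self.min_val))), q.shape
            )
            raise OverflowError(f"fixed-point overflow at index {loc}")
        return q if np.asarray(v).ndim else float(q)


def quantize_model(model: MLPModel, fmt: FixedPointFormat) -> MLPModel:
    """Round all weights and biases to the fixed-point grid (saturating)."""
    return replace(
        model,
        W_hidden=fmt.quantize(model.W_hidden),
        b_hidden=fmt.quantize(model.b_hidden),
        W_out=fmt.quantize(model.W_out),
        b_out=fmt.quantize(model.b_out),
    )


def _act_fixed(z: np.ndarray, act: ActivationSpec, fmt: FixedPointFormat) -> np.ndarray:
    """Cubic activation computed with quantised intermediates (adder +
    multiplier + hard-coded 1/3 constant, as the hardware realises it)."""
    third = fmt.quantize(1.0 / 3.0)
    z2 = fmt.quantize(z * z)
    z3 = fmt.quantize(z2 * z)
    y = fmt.quantize(z + fmt.quantize(z3 * third))
    return np.clip(y, -1.0 + act.clamp_eps, 1.0 - act.clamp_eps)


def forward_fixed(modelq: MLPModel, features: np.ndarray, fmt: FixedPointFormat) -> np.ndarray:
    """Forward pass with fixed-point rounding after every arithmetic stage."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Xq = fmt.quantize(X)
    z1 = fmt.quantize(Xq @ modelq.W_hidden.T + modelq.b_hidden)
    h = _act_fixed(z1, modelq.act, fmt)
    z2 = fmt.quantize(h @ modelq.W_out.T + modelq.b_out)
    y = _act_fixed(z2, modelq.act, fmt)
    return y[0] if np.asarray(features).ndim == 1 else y


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: MLPModel, path) -> None:
    """Structured-text (JSON) serialisation, full double precision."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "shapes": list(model.shape),
        "W_hidden": model.W_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out.tolist(),
        "activation": {
            "form": model.act.form,
            "K": model.act.K,
            "clamp_eps": model.act.clamp_eps,
        },
        "scaler": (
            {"mins": model.scaler.mins.tolist(), "maxs": model.scaler.maxs.tolist()}
            if model.scaler is not None and model.scaler.fitted
            else None
        ),
        "class_names": list(model.class_names),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> MLPModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"malformed model file: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model file version {version!r} (expected {MODEL_FORMAT_VERSION})"
        )
    required = ["shapes", "W_hidden", "b_hidden", "W_out", "b_out", "activation"]
    for key in required:
        if key not in doc:
            raise ModelFormatError(f"model file missing field {key!r}")
    act_doc = doc["activation"]
    for key in ("form", "K", "clamp_eps"):
        if key not in act_doc:
            raise ModelFormatError(f"model file missing field 'activation.{key}'")
    scaler = None
    if doc.get("scaler") is not None:
        scaler = FeatureScaler(
            mins=np.asarray(doc["scaler"]["mins"], dtype=float),
            maxs=np.asarray(doc["scaler"]["maxs"], dtype=float),
        )
    return MLPModel(
        W_hidden=np.asarray(doc["W_hidden"], dtype=float),
        b_hidden=np.asarray(doc["b_hidden"], dtype=float),
        W_out=np.asarray(doc["W_out"], dtype=float),
        b_out=np.asarray(doc["b_out"], dtype=float),
        act=ActivationSpec(
            form=act_doc["form"], K=float(act_doc["K"]), clamp_eps=float(act_doc["clamp_eps"])
        ),
        scaler=scaler,
        class_names=tuple(doc.get("class_names", CLASS_NAMES)),
    )


# ---------------------------------------------------------------------------
# fit diagnostics
# ---------------------------------------------------------------------------

def mse(pred: np.ndarray, target: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.size < 2:
        raise ValueError("pred/target must share a shape with >= 2 elements")
    return float(np.mean((pred - target) ** 2))


def regression_r(pred: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation of flattened predictions against targets."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if p.shape != t.shape or p.size < 2:
        raise ValueError("pred/target must share a shape with >= 2 elements")
    sp = p.std()
    st = t.std()
    if sp == 0 or st == 0:
        raise ValueError("regression R undefined: zero variance input")
    return float(np.mean((p - p.mean()) * (t - t.mean())) / (sp * st))
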
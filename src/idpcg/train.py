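"""Levenberg-Marquardt training of the heart-sound network.

LM minimises the sum of squared output errors with damped Gauss-Newton
steps ``(J'J + lambda I) delta = -J'r``, where the Jacobian ``J`` of the
residuals with respect to all weights and biases is assembled analytically
from the activation derivatives (backpropagation through the two layers).
Rejected steps raise the damping (gradient-descent-like), accepted steps
lower it (Gauss-Newton-like), so the accepted-step training MSE is
non-increasing by construction.

Early stopping follows the usual validation-check pattern: a held-out
fraction of the data is monitored and training stops after ``val_checks``
consecutive epochs without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import ActivationSpec
from .network import FeatureScaler, MLPModel

__all__ = ["TrainConfig", "TrainingRecord", "train_lm", "pack_params", "unpack_params", "lm_jacobian"]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    val_fraction: float = 0.15
    val_checks: int = 6
    seed: int = 0
    goal_mse: float = 1e-8
    init_scale: float = 0.5
    max_rejects: int = 10

    def __post_init__(self):
        if self.lambda0 <= 0 or self.lambda_up <= 1 or not (0 < self.lambda_down < 1):
            raise ValueError("invalid damping schedule")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0,1)")
        if self.max_epochs < 1 or self.val_checks < 1:
            raise ValueError("max_epochs and val_checks must be >= 1")


@dataclass
class TrainingRecord:
    """Per-epoch diagnostics of one LM run."""

    train_mse: list
    val_mse: list
    lambdas: list
    stop_reason: str
    n_epochs: int


def pack_params(model: MLPModel) -> np.ndarray:
    return np.concatenate(
        [model.W_hidden.ravel(), model.b_hidden, model.W_out.ravel(), model.b_out]
    )


def unpack_params(theta: np.ndarray, shape: tuple[int, int, int], act: ActivationSpec,
                  scaler=None) -> MLPModel:
    ni, nh, no = shape
    k = 0
    W1 = theta[k: k + nh * ni].reshape(nh, ni); k += nh * ni
    b1 = theta[k: k + nh]; k += nh
    W2 = theta[k: k + no * nh].reshape(no, nh); k += no * nh
    b2 = theta[k: k + no]
    return MLPModel(W_hidden=W1, b_hidden=b1, W_out=W2, b_out=b2, act=act, scaler=scaler)


def _forward_cached(model: MLPModel, X: np.ndarray):
    z1 = X @ model.W_hidden.T + model.b_hidden
    h = np.asarray(model.act(z1))
    z2 = h @ model.W_out.T + model.b_out
    y = np.asarray(model.act(z2))
    return z1, h, z2, y


def lm_jacobian(model: MLPModel, X: np.ndarray):
    """Residual Jacobian d y / d theta, shape (n_samples*n_out, n_params).

    Residual ordering: sample-major, output-minor — matching
    ``(y - T).ravel()``.  Parameter ordering matches :func:`pack_params`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, ni = X.shape
    nh = model.W_hidden.shape[0]
    no = model.W_out.shape[0]
    z1, h, z2, y = _forward_cached(model, X)
    d1 = np.asarray(model.act.derivative(z1))  # (n, nh)
    d2 = np.asarray(model.act.derivative(z2))  # (n, no)

    n_params = nh * ni + nh + no * nh + no
    J = np.zeros((n * no, n_params))

    # dy_k/dz2_k = d2[:, k];   dz2_k/dW2[k,j] = h[:, j];  dz2_k/db2[k] = 1
    # dy_k/dh_j = d2[:,k] * W2[k,j];  dh_j/dz1_j = d1[:,j];
    # dz1_j/dW1[j,i] = X[:, i];  dz1_j/db1[j] = 1
    off_W1 = 0
    off_b1 = nh * ni
    off_W2 = off_b1 + nh
    off_b2 = off_W2 + no * nh

    # back-signal to hidden pre-activations per output k: (n, nh)
    for k in range(no):
        rows = np.arange(n) * no + k
        gk = d2[:, k][:, None] * model.W_out[k][None, :] * d1  # (n, nh)
        # W1 block: outer product over input dims
        J[rows, off_W1: off_W1 + nh * ni] = (gk[:, :, None] * X[:, None, :]).reshape(n, nh * ni)
        J[rows, off_b1: off_b1 + nh] = gk
        # W2 block: only row k of W2 touches output k
        J[rows, off_W2 + k * nh: off_W2 + (k + 1) * nh] = d2[:, k][:, None] * h
        J[rows, off_b2 + k] = d2[:, k]
    return J, y


def _init_model(shape, act: ActivationSpec, rng: np.random.Generator, scale: float,
                scaler=None) -> MLPModel:
    """Fan-in-scaled uniform init.

    The clamped cubic activation goes dead (zero derivative) once its
    output saturates, so initial pre-activations must stay well inside
    the live region; scaling each layer by 1/sqrt(fan_in) keeps them
    there for inputs in [-1, 1].
    """
    ni, nh, no = shape
    s1 = scale / np.sqrt(ni)
    s2 = scale / np.sqrt(nh)
    return MLPModel(
        W_hidden=rng.uniform(-s1, s1, size=(nh, ni)),
        b_hidden=rng.uniform(-s1, s1, size=nh),
        W_out=rng.uniform(-s2, s2, size=(no, nh)),
        b_out=rng.uniform(-s2, s2, size=no),
        act=act,
        scaler=scaler,
    )


def train_lm(
    X: np.ndarray,
    T: np.ndarray,
    cfg: TrainConfig | None = None,
    act: ActivationSpec | None = None,
    n_hidden: int = 12,
    scaler: FeatureScaler | None = None,
    class_names=None,
) -> tuple[MLPModel, TrainingRecord]:
    """Fit the network to (scaled) features ``X`` and targets ``T`` by LM.

    ``X`` is (n, n_in) already in [-1, 1]; ``T`` is (n, n_out) inside the
    activation range (e.g. +/-0.9 one-hot coding).  Fully reproducible
    from ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    act = act or ActivationSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] != T.shape[0]:
        raise ValueError("X and T row counts differ")
    n = X.shape[0]
    shape = (X.shape[1], n_hidden, T.shape[1])

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 10 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ttr = X[tr_idx], T[tr_idx]
    Xval, Tval = X[val_idx], T[val_idx]

    model = _init_model(shape, act, rng, cfg.init_scale, scaler)
    if class_names is not None:
        model.class_names = tuple(class_names)
    theta = pack_params(model)

    def sse_of(th):
        m = unpack_params(th, shape, act, scaler)
        _, _, _, y = _forward_cached(m, Xtr)
        return float(np.sum((y - Ttr) ** 2)), y

    lam = cfg.lambda0
    sse, _ = sse_of(theta)
    train_path, val_path, lam_path = [], [], []
    best_val = np.inf
    val_bad = 0
    stop = "max_epochs"

    for _epoch in range(cfg.max_epochs):
        model = unpack_params(theta, shape, act, scaler)
        J, y = lm_jacobian(model, Xtr)
        r = (y - Ttr).ravel()
        g = J.T @ r
        JtJ = J.T @ J
        accepted = False
        for _try in range(cfg.max_rejects):
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= cfg.lambda_up
                continue
            cand = theta + delta
            cand_sse, _ = sse_of(cand)
            if cand_sse < sse:
                theta, sse = cand, cand_sse
                lam = max(lam * cfg.lambda_down, 1e-12)
                accepted = True
                break
            lam = min(lam * cfg.lambda_up, 1e12)
        if not accepted:
            stop = "lm_stall"
            break

        tr_mse = sse / (Ttr.size)
        train_path.append(tr_mse)
        lam_path.append(lam)
        if n_val:
            m = unpack_params(theta, shape, act, scaler)
            _, _, _, yv = _forward_cached(m, Xval)
            v_mse = float(np.mean((yv - Tval) ** 2))
            val_path.append(v_mse)
            if v_mse < best_val - 1e-15:
                best_val = v_mse
                val_bad = 0
            else:
                val_bad += 1
                if val_bad >= cfg.val_checks:
                    stop = "val_checks"
                    break
        if tr_mse <= cfg.goal_mse:
            stop = "goal_mse"
            break

    final = unpack_params(theta, shape, act, scaler)
    if class_names is not None:
        final.class_names = tuple(class_names)
    record = TrainingRecord(
        train_mse=train_path,
        val_mse=val_path,
        lambdas=lam_path,
        stop_reason=stop,
        n_epochs=len(train_path),
    )
    return final, record
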
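"""The inverse-delayed (ID) neuron model as a dynamical system.

State of neuron ``i`` is a pair ``(u_i, x_i)``: an internal state and an
output.  With synaptic weights ``w_ij`` (zero diagonal — self-connections
are removed to avoid hysteresis), bias inputs ``h_i`` and time constants
``tau`` (internal) and ``tau_x`` (output, ``tau_x << tau``):

    tau   * du_i/dt = sum_{j != i} w_ij x_j + h_i - u_i
    tau_x * dx_i/dt = u_i - g(x_i),          g(x) = arctanh(x) - K*x

Defining ``phi_i = g'(x_i) + tau_x/tau`` the system is equivalent to a
second-order "mass on a potential" form whose friction coefficient is
``phi_i``.  The Lyapunov energy

    E = -(1/(2 tau)) sum_ij w_ij x_i x_j - (1/tau) sum_i h_i x_i
        + (1/tau) sum_i int_0^{x_i} g(s) ds + (tau_x/2) sum_i (dx_i/dt)^2

obeys ``dE/dt = - sum_i phi_i (dx_i/dt)^2``: the energy decreases wherever
all ``phi_i > 0`` (positive resistance) and can increase where some
``phi_i < 0`` (negative resistance), which is what lets the ID network
climb out of local minima that would trap a Hopfield network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationSpec

__all__ = [
    "IDParams",
    "Synapses",
    "NeuronState",
    "Trajectory",
    "InstabilityError",
    "du_dt",
    "dx_dt",
    "phi",
    "resistance_region",
    "negative_region_bound",
    "energy",
    "energy_rate",
    "integrate",
]


class InstabilityError(RuntimeError):
    """Raised when the integrated internal state diverges."""

    def __init__(self, step: int, max_u: float):
        self.step = step
        self.max_u = max_u
        super().__init__(f"integration diverged at step {step}: max|u| = {max_u:.3g}")


@dataclass(frozen=True)
class IDParams:
    """Time constants and activation-slope constant of the ID model.

    ``a_self`` is the self-connection weight a_ii, fixed at zero (the model
    is run self-connectionless to avoid hysteresis); it is kept as a field
    so the constraint is explicit.
    """

    tau: float = 1.0
    tau_x: float = 0.1
    K: float = 0.0
    a_self: float = 0.0

    def __post_init__(self):
        if self.tau <= 0 or self.tau_x <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_x >= self.tau:
            raise ValueError("requires tau_x < tau")
        if self.K < 0:
            raise ValueError("K must be nonnegative")
        if self.a_self != 0.0:
            raise ValueError("self-connections are not supported (a_self must be 0)")

    @property
    def ratio(self) -> float:
        """tau_x / tau, the friction offset in phi."""
        return self.tau_x / self.tau

    def activation(self, form: str = "exact_arctanh", clamp_eps: float = 1e-6) -> ActivationSpec:
        return ActivationSpec(form=form, K=self.K, clamp_eps=clamp_eps)


@dataclass
class Synapses:
    """Synaptic weight matrix ``W`` (zero diagonal) and bias vector ``h``."""

    W: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.h.shape != (self.W.shape[0],):
            raise ValueError("h length must match W")
        if not np.all(np.isfinite(self.W)) or not np.all(np.isfinite(self.h)):
            raise ValueError("W and h must be finite")
        if np.any(np.diag(self.W) != 0.0):
            raise ValueError("diagonal of W must be zero (self-connectionless)")

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class NeuronState:
    """Internal states ``u``, outputs ``x`` and the current time ``t``."""

    u: np.ndarray
    x: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.u.shape != self.x.shape or self.u.ndim != 1:
            raise ValueError("u and x must be 1-d vectors of equal length")


@dataclass
class Trajectory:
    """Integrated path: times, state history and (optionally) energies."""

    times: np.ndarray
    u: np.ndarray  # (n_steps+1, n)
    x: np.ndarray
    energies: np.ndarray | None = None
    x_rates: np.ndarray | None = None
    params: IDParams | None = None
    meta: dict = field(default_factory=dict)

    def state(self, k: int) -> NeuronState:
        return NeuronState(u=self.u[k].copy(), x=self.x[k].copy(), t=float(self.times[k]))

    def to_text(self, path) -> None:
        """Write the trajectory as a TSV (time, u_i..., x_i..., E)."""
        n = self.u.shape[1]
        cols = ["time"] + [f"u{i}" for i in range(n)] + [f"x{i}" for i in range(n)]
        blocks = [self.times[:, None], self.u, self.x]
        if self.energies is not None:
            cols.append("E")
            blocks.append(self.energies[:, None])
        data = np.hstack(blocks)
        header = "\t".join(cols)
        np.savetxt(path, data, delimiter="\t", header=header, comments="")


def du_dt(state: NeuronState, syn: Synapses, p: IDParams) -> np.ndarray:
    """Internal-state derivative ``(W x + h - u) / tau`` (zero-diagonal W)."""
    if state.u.shape[0] != syn.n:
        raise ValueError("state size does not match synapses")
    return (syn.W @ state.x + syn.h - state.u) / p.tau


def dx_dt(state: NeuronState, p: IDParams, act: ActivationSpec) -> np.ndarray:
    """Output derivative ``(u - g(x)) / tau_x``."""
    return (state.u - np.asarray(act.g(state.x))) / p.tau_x


def phi(x, p: IDParams, act: ActivationSpec):
    """Friction coefficient ``phi = g'(x) + tau_x/tau`` of the 2nd-order form."""
    return np.asarray(act.g_prime(x)) + p.ratio


def resistance_region(x: float, p: IDParams, act: ActivationSpec) -> str:
    """Classify a scalar output value as ``"positive"`` or ``"negative"``.

    Negative resistance means ``g'(x) < -tau_x/tau`` (phi < 0), where the
    Lyapunov energy locally increases.  The boundary ``phi == 0`` counts
    as positive (energy rate is zero there, so descent is preserved); a
    small tolerance absorbs rounding in the phi evaluation.
    """
    val = float(act.g_prime(x)) + p.ratio
    return "negative" if val < -1e-12 else "positive"


def negative_region_bound(K: float, p: IDParams) -> float | None:
    """Half-width of the negative-resistance interval around the origin.

    Solving ``1/(1-x^2) = K - tau_x/tau`` gives ``|x| < sqrt(1 - 1/(K-r))``
    with ``r = tau_x/tau``; returns None when ``K - r <= 1`` (no negative
    region exists).
    """
    gap = K - p.ratio
    if gap <= 1.0:
        return None
    return float(np.sqrt(1.0 - 1.0 / gap))


def energy(
    state: NeuronState,
    syn: Synapses,
    p: IDParams,
    act: ActivationSpec,
    x_rate: np.ndarray,
) -> float:
    """Lyapunov energy of the ID network at one state.

    ``x_rate`` must be ``dx/dt`` at the same state; the kinetic term
    ``(tau_x/2) sum (dx/dt)^2`` is what distinguishes the ID energy from
    the Hopfield one.  The g-integral uses its closed form, and the bias
    enters as ``-(1/tau) sum h_i x_i``.
    """
    x = state.x
    x_rate = np.asarray(x_rate, dtype=float)
    if x_rate.shape != x.shape:
        raise ValueError("x_rate shape mismatch")
    quad = -0.5 * float(x @ (syn.W @ x)) / p.tau
    bias = -float(syn.h @ x) / p.tau
    gint = float(np.sum(act.g_antiderivative(x))) / p.tau
    kin = 0.5 * p.tau_x * float(x_rate @ x_rate)
    return quad + bias + gint + kin


def energy_rate(
    state: NeuronState, p: IDParams, act: ActivationSpec, x_rate: np.ndarray
) -> float:
    """``dE/dt = - sum_i phi_i (dx_i/dt)^2``."""
    x_rate = np.asarray(x_rate, dtype=float)
    ph = phi(state.x, p, act)
    return -float(np.sum(ph * x_rate**2))


def integrate(
    state0: NeuronState,
    syn: Synapses,
    p: IDParams,
    act: ActivationSpec,
    dt: float,
    n_steps: int,
    record_energy: bool = True,
) -> Trajectory:
    """Fixed-step RK4 integration of the ID dynamics.

    ``dt`` must satisfy ``dt <= tau_x/10`` (stability guard for the stiff
    output equation); outputs are re-clamped into the activation's guard
    band after every step.  Divergence (any ``|u_i| > 1e6``) raises
    :class:`InstabilityError` with the offending step index.
    """
    if dt > p.tau_x / 10.0 + 1e-15:
        raise ValueError("dt must be <= tau_x/10")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = state0.u.shape[0]
    if syn.n != n:
        raise ValueError("synapse size mismatch")
    lim = 1.0 - act.clamp_eps

    def deriv(u: np.ndarray, x: np.ndarray):
        xc = np.clip(x, -lim, lim)
        du = (syn.W @ xc + syn.h - u) / p.tau
        dx = (u - np.asarray(act.g(xc))) / p.tau_x
        return du, dx

    times = state0.t + dt * np.arange(n_steps + 1)
    U = np.empty((n_steps + 1, n))
    X = np.empty((n_steps + 1, n))
    U[0] = state0.u
    X[0] = np.clip(state0.x, -lim, lim)

    for k in range(n_steps):
        u, x = U[k], X[k]
        k1u, k1x = deriv(u, x)
        k2u, k2x = deriv(u + 0.5 * dt * k1u, x + 0.5 * dt * k1x)
        k3u, k3x = deriv(u + 0.5 * dt * k2u, x + 0.5 * dt * k2x)
        k4u, k4x = deriv(u + dt * k3u, x + dt * k3x)
        U[k + 1] = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
        X[k + 1] = np.clip(x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x), -lim, lim)
        if np.any(np.abs(U[k + 1]) > 1e6):
            raise InstabilityError(k + 1, float(np.max(np.abs(U[k + 1]))))

    energies = None
    rates = np.empty_like(X)
    for k in range(n_steps + 1):
        _, rates[k] = deriv(U[k], X[k])
    if record_energy:
        energies = np.array(
            [
                energy(NeuronState(U[k], X[k], times[k]), syn, p, act, rates[k])
                for k in range(n_steps + 1)
            ]
        )
    return Trajectory(
        times=times, u=U, x=X, energies=energies, x_rates=rates, params=p,
        meta={"dt": dt, "n_steps": n_steps},
    )
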
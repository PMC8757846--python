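"""Inverse-tanh activation functions and the N-shaped inverse output map.

The inverse-delayed (ID) neuron model replaces the usual sigmoid activation
with the *inverse* of the sigmoid.  With ``f(x) = arctanh(x)`` the model's
output nullcline is governed by

    g(x) = arctanh(x) - K*x,

where ``K >= 0`` bends ``g`` into an N-shape.  For ``K`` large enough the
slope ``g'(x) = 1/(1-x^2) - K`` dips below ``-tau_x/tau`` on an interval
around the origin, producing the negative-resistance region that lets the
network escape local minima of its Lyapunov energy.

Hardware realisations keep only the first two terms of the arctanh series,

    f(x) ~= x + x**3 / 3,

which needs one multiplier and one adder.  Both the exact and the truncated
forms are provided; outputs (and arctanh inputs) are clamped to
``[-1+eps, 1-eps]`` so the map stays inside the open interval (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationSpec",
    "arctanh_exact",
    "arctanh_taylor",
    "clamp_output",
    "g_inverse_output",
    "g_prime",
    "taylor_abs_error",
    "taylor_error_bound",
]

_DEFAULT_EPS = 1e-6


def _asarray_checked(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value in {name}")
    return arr


def _maybe_scalar(arr: np.ndarray, like) -> "np.ndarray | float":
    if np.isscalar(like) or (isinstance(like, np.ndarray) and like.ndim == 0):
        return float(arr)
    return arr


def clamp_output(y, eps: float = _DEFAULT_EPS):
    """Clamp ``y`` into ``[-1+eps, 1-eps]``.  Idempotent."""
    arr = _asarray_checked(y, "y")
    return _maybe_scalar(np.clip(arr, -1.0 + eps, 1.0 - eps), y)


def arctanh_exact(x, clamp_eps: float = _DEFAULT_EPS):
    """Exact inverse hyperbolic tangent, ``0.5*ln((1+x)/(1-x))``.

    Inputs are clamped inward to ``|x| <= 1 - clamp_eps`` so the logarithm
    stays finite; the function is odd.
    """
    arr = _asarray_checked(x)
    xc = np.clip(arr, -1.0 + clamp_eps, 1.0 - clamp_eps)
    return _maybe_scalar(0.5 * np.log((1.0 + xc) / (1.0 - xc)), x)


def arctanh_taylor(x, clamp_eps: float = _DEFAULT_EPS):
    """Cubic truncation ``x + x**3/3`` of the arctanh series, output-clamped.

    This is the form the fixed-point hardware realises (constant 1/3, one
    multiplier, one adder).  The raw polynomial exceeds 1 for ``|x| > 0.908``
    so the result is clamped into ``[-1+eps, 1-eps]``.
    """
    arr = _asarray_checked(x)
    raw = arr + arr**3 / 3.0
    return _maybe_scalar(np.clip(raw, -1.0 + clamp_eps, 1.0 - clamp_eps), x)


def g_inverse_output(x, K: float, clamp_eps: float = _DEFAULT_EPS):
    """The N-shaped inverse output map ``g(x) = arctanh(x) - K*x``."""
    if K < 0:
        raise ValueError("K must be nonnegative")
    arr = _asarray_checked(x)
    xc = np.clip(arr, -1.0 + clamp_eps, 1.0 - clamp_eps)
    return _maybe_scalar(0.5 * np.log((1.0 + xc) / (1.0 - xc)) - K * xc, x)


def g_prime(x, K: float):
    """Analytic derivative ``g'(x) = 1/(1-x**2) - K``; domain ``|x| < 1``."""
    arr = _asarray_checked(x)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("g_prime requires |x| < 1")
    return _maybe_scalar(1.0 / (1.0 - arr**2) - K, x)


def taylor_abs_error(x, clamp_eps: float = _DEFAULT_EPS):
    """|arctanh(x) - (x + x**3/3)| — the truncation error of the cubic form.

    Bounded above by ``|x|**5 / (5*(1-x**2))`` (geometric tail of the odd
    power series); see :func:`taylor_error_bound`.
    """
    arr = _asarray_checked(x)
    exact = np.asarray(arctanh_exact(arr, clamp_eps))
    poly = arr + arr**3 / 3.0
    return _maybe_scalar(np.abs(exact - poly), x)


def taylor_error_bound(x):
    """Remainder bound ``|x|**5 / (5*(1-x**2))`` for the cubic truncation."""
    arr = _asarray_checked(x)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("bound requires |x| < 1")
    return _maybe_scalar(np.abs(arr) ** 5 / (5.0 * (1.0 - arr**2)), x)


@dataclass(frozen=True)
class ActivationSpec:
    """Which activation form a network uses, and its constants.

    Parameters
    ----------
    form:
        ``"taylor_cubic"`` (the hardware-friendly default) or
        ``"exact_arctanh"``.
    K:
        Slope-modification constant of the inverse output map; only used
        by the dynamics (the feedforward activation itself is ``f``, not
        ``g``).  Must be nonnegative.
    clamp_eps:
        Guard band keeping inputs/outputs strictly inside (-1, 1).
    """

    form: str = "taylor_cubic"
    K: float = 0.0
    clamp_eps: float = 1e-6

    def __post_init__(self):
        if self.form not in ("taylor_cubic", "exact_arctanh"):
            raise ValueError(f"unknown activation form {self.form!r}")
        if self.K < 0:
            raise ValueError("K must be nonnegative")
        if not (0.0 < self.clamp_eps < 0.01):
            raise ValueError("clamp_eps must lie in (0, 0.01)")

    # -- feedforward use -------------------------------------------------
    def __call__(self, z):
        """Apply the activation to pre-activations ``z`` (any real)."""
        if self.form == "taylor_cubic":
            return arctanh_taylor(z, self.clamp_eps)
        # exact form: arctanh needs |z| < 1, clamp input then output
        return _maybe_scalar(
            np.clip(
                np.asarray(arctanh_exact(z, self.clamp_eps)),
                -1.0 + self.clamp_eps,
                1.0 - self.clamp_eps,
            ),
            z,
        )

    def derivative(self, z):
        """d(activation)/dz, zero wherever the output is clamped."""
        arr = _asarray_checked(z, "z")
        if self.form == "taylor_cubic":
            raw = arr + arr**3 / 3.0
            d = 1.0 + arr**2
            d = np.where(np.abs(raw) > 1.0 - self.clamp_eps, 0.0, d)
        else:
            inside = np.abs(arr) <= 1.0 - self.clamp_eps
            xc = np.clip(arr, -1.0 + self.clamp_eps, 1.0 - self.clamp_eps)
            val = 0.5 * np.log((1.0 + xc) / (1.0 - xc))
            d = np.where(
                inside & (np.abs(val) <= 1.0 - self.clamp_eps),
                1.0 / (1.0 - xc**2),
                0.0,
            )
        return _maybe_scalar(d, z)

    # -- dynamics use ----------------------------------------------------
    def g(self, x):
        """Inverse output map ``g(x) = arctanh(x) - K*x``."""
        return g_inverse_output(x, self.K, self.clamp_eps)

    def g_prime(self, x):
        return g_prime(x, self.K)

    def g_antiderivative(self, x):
        """Closed form of ``int_0^x g(s) ds``.

        ``x*arctanh(x) + 0.5*ln(1-x^2) - K*x^2/2`` — used by the Lyapunov
        energy so no quadrature is needed at run time.
        """
        arr = _asarray_checked(x)
        xc = np.clip(arr, -1.0 + self.clamp_eps, 1.0 - self.clamp_eps)
        at = 0.5 * np.log((1.0 + xc) / (1.0 - xc))
        val = xc * at + 0.5 * np.log(1.0 - xc**2) - self.K * xc**2 / 2.0
        return _maybe_scalar(val, x)
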
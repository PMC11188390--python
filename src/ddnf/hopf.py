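"""Hopf bifurcation analysis of the delayed negative-feedback models.

For the Mackey-Glass equation dx/dt = 1/(1 + x(t-tau)^p) - b x, the steady
state x* solves x (1 + x^p) = 1/b and the linearization about it has the
characteristic equation

    lambda = -A exp(-lambda tau) - b,      A = p x*^(p-1) / (1 + x*^p)^2.

Purely imaginary roots lambda = i omega (z = omega tau) satisfy

    x^p = -1 / (p cos z + 1) > 0      (real part)
    tau = -z / (b tan z)              (imaginary part)

with z in (arccos(-1/p), pi).  Sweeping z traces the closed Hopf boundary in
the (tau, b) plane; at fixed tau it carries two points, a lower one with
b = O(1/p) and an upper one with b near 1.  Large-p asymptotics give the
closed forms b = pi/(2 p tau) (lower) and the parametric upper-branch
approximation implemented in :func:`upper_branch_approx`, which are also the
Hopf points of the two reduced (Wright-type) equations lifted back to the
full model.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import hill_steady_state, lift_reduced_parameter

__all__ = [
    "HopfPoint",
    "HopfCurve",
    "NoHopfPointError",
    "sigmoidal_hopf_delay",
    "hill_steady_state",
    "characteristic_residual",
    "hopf_point_at_tau",
    "hopf_curve",
    "lower_branch_approx",
    "upper_branch_approx",
    "reduced_hopf",
    "hopf_period_approx",
]


class NoHopfPointError(RuntimeError):
    """No Hopf point exists on the requested branch at this delay."""


@dataclass(frozen=True)
class HopfPoint:
    """A point on the Hopf boundary of the Mackey-Glass equation.

    ``z = omega * tau`` lies in (pi/2, pi); ``branch`` is "lower" (b = O(1/p),
    z near arccos(-1/p)) or "upper" (b near 1, z near pi).
    """

    z: float
    omega: float
    tau: float
    b: float
    x_ss: float
    p: float
    branch: str

    @property
    def period(self) -> float:
        """Period 2*pi/omega of the emerging oscillation (absolute units)."""
        return 2.0 * math.pi / self.omega


@dataclass(frozen=True)
class HopfCurve:
    """The Hopf boundary in the (tau, b) plane, ordered by increasing z."""

    p: float
    z: np.ndarray
    tau: np.ndarray
    b: np.ndarray
    x_ss: np.ndarray
    omega: np.ndarray

    def __len__(self) -> int:
        return len(self.z)


def sigmoidal_hopf_delay(kappa: float) -> float:
    """First Hopf delay tau0 = pi/(2*kappa) of dx/dt = -tanh(kappa x(t-tau))."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return math.pi / (2.0 * kappa)


def _slope(x: float, p: float) -> float:
    """A = p x^(p-1) / (1 + x^p)^2 = -f'(x), evaluated in log space."""
    lx = math.log(x)
    m = p * lx
    if m > 0:
        lse = m + math.log1p(math.exp(-min(m, 700.0)))
    else:
        lse = math.log1p(math.exp(max(m, -700.0)))
    return math.exp(math.log(p) + (p - 1.0) * lx - 2.0 * lse)


def characteristic_residual(lam: complex, b: float, p: float, tau: float) -> complex:
    """lambda + A exp(-lambda tau) + b at the steady state; zero iff lambda is a root."""
    if b <= 0 or p <= 0 or tau <= 0:
        raise ValueError("b, p, tau must be positive")
    x = hill_steady_state(b, p)
    a = _slope(x, p)
    return lam + a * cmath.exp(-lam * tau) + b


def _chain_from_z(z: float, p: float) -> tuple[float, float, float]:
    """(x, b, tau) on the Hopf boundary for a given z in (arccos(-1/p), pi)."""
    denom = p * math.cos(z) + 1.0
    xp = -1.0 / denom  # requires denom < 0
    x = math.exp(math.log(xp) / p)
    b = 1.0 / (x * (1.0 + xp))
    tau = -z / (b * math.tan(z))
    return x, b, tau


def hopf_point_at_tau(tau: float, p: float, branch: str, scan: int = 400) -> HopfPoint:
    """Numerical Hopf point of the Mackey-Glass equation at fixed delay.

    Solves tau(z) = tau on (arccos(-1/p), pi) by a bracketing scan followed
    by bisection; tau(z) diverges at both ends of the interval, so above the
    minimum there are exactly two roots.  The lower branch is the smaller-z
    root (x^p = O(p), small b); the upper branch is the larger-z root
    (x^p = O(1/p), b near 1).

    Raises
    ------
    NoHopfPointError
        If tau lies below the minimum of tau(z) (no sign change in the scan).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if p <= 1:
        raise ValueError("p must exceed 1 for a Hopf point to exist")
    if branch not in ("lower", "upper"):
        raise ValueError("branch must be 'lower' or 'upper'")
    z_min = math.acos(-1.0 / p)
    eps = (math.pi - z_min) * 1e-9
    zs = np.linspace(z_min + eps, math.pi - eps, scan + 1)
    g = np.array([_chain_from_z(z, p)[2] - tau for z in zs])
    sign_changes = np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
    if len(sign_changes) == 0:
        raise NoHopfPointError(
            f"no Hopf point at tau = {tau} for p = {p}: delay below the Hopf boundary"
        )
    idx = sign_changes[0] if branch == "lower" else sign_changes[-1]
    z = brentq(lambda zz: _chain_from_z(zz, p)[2] - tau, zs[idx], zs[idx + 1], xtol=1e-14)
    x, b, _ = _chain_from_z(z, p)
    return HopfPoint(z=z, omega=z / tau, tau=tau, b=b, x_ss=x, p=p, branch=branch)


def hopf_curve(p: float, n_points: int = 200) -> HopfCurve:
    """Trace the Hopf boundary by sweeping z over (arccos(-1/p), pi)."""
    if p <= 1:
        raise ValueError("p must exceed 1")
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    z_min = math.acos(-1.0 / p)
    eps = (math.pi - z_min) * 1e-6
    zs = np.linspace(z_min + eps, math.pi - eps, n_points)
    xs = np.empty(n_points)
    bs = np.empty(n_points)
    taus = np.empty(n_points)
    for i, z in enumerate(zs):
        xs[i], bs[i], taus[i] = _chain_from_z(z, p)
    return HopfCurve(p=p, z=zs, tau=taus, b=bs, x_ss=xs, omega=zs / taus)


def lower_branch_approx(tau: float, p: float) -> float:
    """Large-p closed form of the lower Hopf point: b = pi / (2 p tau)."""
    if tau <= 0 or p <= 0:
        raise ValueError("tau and p must be positive")
    return math.pi / (2.0 * p * tau)


def _delay_phase_root(tau: float) -> float:
    """Solve -z / tan(z) = tau for z in (pi/2, pi), to 1e-12."""
    lo = math.pi / 2 + 1e-12
    hi = math.pi - 1e-12
    return brentq(lambda z: -z / math.tan(z) - tau, lo, hi, xtol=1e-13)


def upper_branch_approx(tau: float, p: float) -> tuple[float, float, float]:
    """Large-p parametric approximation of the upper Hopf point.

    Solves -z0/tan(z0) = tau for z0 in (pi/2, pi), sets x1 = -ln(-cos z0),
    and returns ``(b, z0, x1)`` with b = 1 + (ln p - x1 - exp(x1)) / p.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if p <= 1:
        raise ValueError("p must exceed 1")
    z0 = _delay_phase_root(tau)
    x1 = -math.log(-math.cos(z0))
    b = 1.0 + (math.log(p) - x1 - math.exp(x1)) / p
    return b, z0, x1


def reduced_hopf(tau: float, branch: str) -> float:
    """Hopf value of the reduced control parameter b1 at delay tau.

    Lower branch (Wright-type equation u' = exp(-u(t-tau)) - b1):
    b1 = pi/(2*tau).  Upper branch (u' = -exp(u(t-tau)) - u - b1): solve
    -z/tan(z) = tau on (pi/2, pi), set u = -ln(-cos z), return
    b1 = -(u + exp(u)).

    Lifting these through the parameter maps reproduces the large-p
    approximations of the full model exactly.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if branch == "lower":
        return math.pi / (2.0 * tau)
    if branch == "upper":
        z = _delay_phase_root(tau)
        u = -math.log(-math.cos(z))
        return -(u + math.exp(u))
    raise ValueError("branch must be 'lower' or 'upper'")


def hopf_period_approx(p: float) -> float:
    """Oscillation period at the lower Hopf point, in units of the delay.

    2*pi / (pi/2 + 1/p); tends to 4 (the sawtooth/threshold period) as
    p -> infinity and increases strictly with p.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    return 2.0 * math.pi / (math.pi / 2.0 + 1.0 / p)


def _lifted_lower(tau: float, p: float) -> float:
    """Lower reduced Hopf point lifted to the full decay rate (= closed form)."""
    return lift_reduced_parameter(reduced_hopf(tau, "lower"), p, "lower")
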
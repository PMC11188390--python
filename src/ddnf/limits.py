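"""Closed-form strong-feedback-limit solutions.

Two limits are covered:

* the sign/sigmoidal limit kappa -> infinity, where the stable oscillation is
  a 4*tau-periodic sawtooth; matched asymptotics give a uniform approximation
  whose corner layers have the -ln(2 cosh) profile, and a local Hopf
  amplitude law valid in a window of width O(1/kappa) above the Hopf delay;

* the Heaviside limit p -> infinity of the Hill feedback, where the limit
  cycle consists of exponential segments and the extrema and period are
  available in closed form for 0 < b < 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SawtoothApprox",
    "ThresholdCycle",
    "sawtooth_outer",
    "sawtooth_uniform",
    "hopf_local_amplitude",
    "threshold_cycle",
]


def _log2cosh(y):
    """log(2 cosh(y)) evaluated without overflow: |y| + log1p(exp(-2|y|))."""
    ay = np.abs(y)
    return ay + np.log1p(np.exp(-2.0 * ay))


def sawtooth_outer(t, tau: float):
    """The 4*tau-periodic piecewise-linear sawtooth (strong-feedback outer solution).

    Rises with slope +1 from 0 at t = 0 to +tau at t = tau, falls with slope
    -1 to -tau at t = 3*tau, and repeats; extrema +/-tau at t = (1 + 2n)*tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = np.mod(np.asarray(t, dtype=float), 4.0 * tau)
    out = np.where(s <= tau, s, np.where(s <= 3.0 * tau, 2.0 * tau - s, s - 4.0 * tau))
    return float(out) if out.ndim == 0 else out


def sawtooth_uniform(t, tau: float, kappa: float):
    """Uniform (outer + corner-layer) approximation of the sawtooth oscillation.

    On one period: tau - ln(2 cosh(kappa (t - tau)))/kappa for 0 < t < 2*tau
    and its odd image -tau + ln(2 cosh(kappa (t - 3*tau)))/kappa for
    2*tau < t < 4*tau, extended 4*tau-periodically.  The remaining error is
    O(exp(-kappa)), far below the naive O(1/kappa) layer-width estimate.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if kappa * tau < 2.0:
        warnings.warn(
            "sawtooth_uniform assumes kappa*tau >> 1; "
            f"kappa*tau = {kappa * tau:.3g} is outside the asymptotic regime",
            stacklevel=2,
        )
    s = np.mod(np.asarray(t, dtype=float), 4.0 * tau)
    up = tau - _log2cosh(kappa * (s - tau)) / kappa
    down = -tau + _log2cosh(kappa * (s - 3.0 * tau)) / kappa
    out = np.where(s <= 2.0 * tau, up, down)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SawtoothApprox:
    """Callable 4*tau-periodic uniform approximation for fixed (tau, kappa)."""

    tau: float
    kappa: float

    def __call__(self, t):
        return sawtooth_uniform(t, self.tau, self.kappa)

    @property
    def period(self) -> float:
        return 4.0 * self.tau

    @property
    def extremum(self) -> float:
        """Peak value tau - ln(2)/kappa, attained at t = tau (trough at 3*tau)."""
        return self.tau - math.log(2.0) / self.kappa


def hopf_local_amplitude(tau: float, kappa: float) -> tuple[float, bool]:
    """Local Hopf amplitude 2*sqrt((tau - tau0)/tau0) of the sigmoidal model.

    ``tau0 = pi/(2*kappa)`` is the Hopf delay.  The value is the amplitude of
    the rescaled state y = kappa*x: substituting y and s = kappa*t brings the
    model to the canonical form dy/ds = -tanh(y(s - kappa*tau)), whose local
    Hopf amplitude is exactly this law; divide by kappa for the amplitude of
    x itself.  Returns ``(amplitude, valid)`` where ``valid`` is False once
    (tau - tau0)/tau0 exceeds 1/kappa — outside that window the local
    expansion loses uniformity and the oscillation crosses over to the
    sawtooth regime.  Below ``tau0`` the steady state is stable and the
    amplitude is zero.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    tau0 = math.pi / (2.0 * kappa)
    if tau < tau0:
        return 0.0, True
    rel = (tau - tau0) / tau0
    return 2.0 * math.sqrt(rel), rel <= 1.0 / kappa


@dataclass(frozen=True)
class ThresholdCycle:
    """Closed-form limit cycle of the Heaviside-feedback model (0 < b < 1).

    One period consists of four phases: production stays on for tau after the
    upward threshold crossing (rise to x_max), then off for tau + delta2
    (decay through 1 down to x_min), then on again for delta1 until x returns
    to 1.  Hence period = 2*tau + delta1 + delta2.
    """

    b: float
    tau: float
    x_min: float
    x_max: float
    period: float
    delta1: float  # rise time from x_min back up to the threshold
    delta2: float  # decay time from x_max down to the threshold

    @property
    def phase_durations(self) -> tuple[float, float, float, float]:
        """(tau, delta1, tau, delta2): overshoot, rise-to-1, undershoot, fall-to-1."""
        return (self.tau, self.delta1, self.tau, self.delta2)


def threshold_cycle(b: float, tau: float) -> ThresholdCycle:
    """Extrema and period of the Heaviside-limit oscillation.

    x_min = exp(-b*tau), x_max = (1 - 1/b) exp(-b*tau) + 1/b, and

        P = -(1/b) * ln[ x_min (1 - b x_max) / (x_max (1 - b x_min)) ],

    which coincides exactly with the phase-duration sum
    2*tau + delta1 + delta2 (two independent derivations of the same cycle).

    Raises
    ------
    ValueError
        If b >= 1 (production can no longer lift the state above the
        threshold: the period diverges like -ln(1 - b) as b -> 1-).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 < b < 1.0:
        raise ValueError("the threshold limit cycle exists only for 0 < b < 1")
    e = math.exp(-b * tau)
    x_min = e
    x_max = (1.0 - 1.0 / b) * e + 1.0 / b
    delta2 = math.log(x_max) / b
    delta1 = -math.log((1.0 - b) / (1.0 - b * x_min)) / b
    period = -math.log(x_min * (1.0 - b * x_max) / (x_max * (1.0 - b * x_min))) / b
    return ThresholdCycle(
        b=b, tau=tau, x_min=x_min, x_max=x_max, period=period, delta1=delta1, delta2=delta2
    )
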
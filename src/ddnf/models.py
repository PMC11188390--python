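"""Scalar delayed negative-feedback models.

The family implemented here is the first-order delay differential equation

    dx/dt = f(x(t - tau)) - b * x(t),

where ``f`` is a decreasing (negative feedback) nonlinearity and ``tau > 0``
is the delay.  Supported feedback kinds:

``sigmoidal``
    f(x) = -tanh(kappa * x), b = 0.  A minimal model of delayed mutual
    inhibition; the state oscillates around zero.
``hill``
    f(x) = 1 / (1 + x**p), b > 0.  The Mackey-Glass equation for delayed
    control of blood-cell production; ``p`` is the Hill exponent.
``wazewska``
    f(x) = a * exp(-c * x), b > 0.  The Wazewska-Lasota red-blood-cell model.
``threshold``
    f(x) = 1 if x <= 1 else 0, the Heaviside (p -> infinity) limit of the
    Hill feedback.
``sign``
    f(x) = -sign(x), the kappa -> infinity limit of the sigmoidal feedback
    (threshold level 0, b = 0).
``wright_reduced``
    u' = exp(-u(t - tau)) - b1, the Wright-type equation governing the
    strong-feedback dynamics near the lower Hopf point of the Hill model.
``upper_reduced``
    u' = -exp(u(t - tau)) - u - b1, the reduction valid near the upper Hopf
    point of the Hill model.

The reduced variables map back to the full Mackey-Glass state and decay rate
through :func:`lift_reduced_state` and :func:`lift_reduced_parameter`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Union

from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "SigmoidalParams",
    "HillParams",
    "WazewskaParams",
    "ThresholdParams",
    "SignParams",
    "ReducedParams",
    "ModelSpec",
    "hill_feedback",
    "sigmoidal_feedback",
    "rhs",
    "make_rhs",
    "hill_steady_state",
    "steady_state",
    "lift_reduced_state",
    "project_full_state",
    "lift_reduced_parameter",
    "project_full_parameter",
    "model_to_dict",
    "model_from_dict",
]

# exp() overflows just above 709; p*log(x) is clamped well inside that.
_EXP_CLAMP = 700.0


class DomainError(ValueError):
    """State left the domain on which the feedback function is defined."""


def _clamp(v: float, lo: float, hi: float) -> float:
    return lo if v < lo else hi if v > hi else v


def hill_feedback(x_delayed: float, p: float) -> float:
    """Hill production term 1 / (1 + x**p), evaluated in log space.

    Stable for arbitrarily steep exponents (the product ``p*log(x)`` is
    clamped before exponentiation), so ``p`` of several hundred is safe.

    Raises
    ------
    DomainError
        If ``x_delayed <= 0`` (the model describes a positive population).
    """
    if x_delayed <= 0.0:
        raise DomainError(f"hill feedback requires a positive delayed state, got {x_delayed}")
    m = _clamp(p * math.log(x_delayed), -_EXP_CLAMP, _EXP_CLAMP)
    if m >= 0.0:
        e = math.exp(-m)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(m))


def sigmoidal_feedback(x_delayed: float, kappa: float) -> float:
    """Saturating inhibition -tanh(kappa * x); odd and strictly decreasing."""
    return -math.tanh(kappa * x_delayed)


@dataclass(frozen=True)
class SigmoidalParams:
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class HillParams:
    p: float
    b: float

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("Hill exponent p must be positive")
        if self.b < 0:
            raise ValueError("decay rate b must be nonnegative")


@dataclass(frozen=True)
class WazewskaParams:
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("a, b, c must all be positive")


@dataclass(frozen=True)
class ThresholdParams:
    """Heaviside feedback with production threshold fixed at x = 1.

    Sustained oscillations require ``0 < b < 1``; for ``b >= 1`` the steady
    state ``x = 1/b`` lies below the threshold and the solution settles.
    """

    b: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("decay rate b must be positive")


@dataclass(frozen=True)
class SignParams:
    """Sign feedback -sign(x(t - tau)); no free parameters (b = 0)."""


@dataclass(frozen=True)
class ReducedParams:
    """Parameters of the reduced (strong-feedback) equations.

    ``b1`` is the rescaled control parameter; ``p`` is carried along only so
    reduced solutions can be lifted back to the full model.
    """

    b1: float
    p: float = 20.0

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("Hill exponent p must be positive")


_PARAM_TYPES = {
    "sigmoidal": SigmoidalParams,
    "hill": HillParams,
    "wazewska": WazewskaParams,
    "threshold": ThresholdParams,
    "sign": SignParams,
    "wright_reduced": ReducedParams,
    "upper_reduced": ReducedParams,
}

Params = Union[
    SigmoidalParams, HillParams, WazewskaParams, ThresholdParams, SignParams, ReducedParams
]


@dataclass(frozen=True)
class ModelSpec:
    """A scalar delayed-feedback model: feedback kind, parameters, delay.

    Parameters are validated once at construction; the right-hand side
    evaluation itself performs only domain checks on the state.
    """

    kind: str
    params: Params
    delay: float

    def __post_init__(self) -> None:
        if self.kind not in _PARAM_TYPES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        expected = _PARAM_TYPES[self.kind]
        if not isinstance(self.params, expected):
            raise TypeError(f"kind {self.kind!r} requires {expected.__name__}")
        if not (self.delay > 0 and math.isfinite(self.delay)):
            raise ValueError("delay must be a positive finite real")

    @property
    def is_piecewise(self) -> bool:
        """True for kinds whose delayed dependence is piecewise constant."""
        return self.kind in ("threshold", "sign")

    @property
    def positive_state(self) -> bool:
        """True for kinds whose state must remain strictly positive."""
        return self.kind in ("hill", "wazewska")

    def rhs(self, x_now: float, x_delayed: float) -> float:
        return rhs(self, x_now, x_delayed)


def rhs(model: ModelSpec, x_now: float, x_delayed: float) -> float:
    """Instantaneous time derivative dx/dt of the given model.

    For the ``threshold`` and ``sign`` kinds the delayed dependence is exactly
    piecewise constant; the value exactly at the threshold is resolved as
    "production on" (a measure-zero convention, fixed for reproducibility).
    """
    k = model.kind
    p = model.params
    if k == "hill":
        return hill_feedback(x_delayed, p.p) - p.b * x_now
    if k == "sigmoidal":
        return sigmoidal_feedback(x_delayed, p.kappa)
    if k == "wazewska":
        if x_delayed <= 0.0:
            raise DomainError("wazewska model requires a positive delayed state")
        return p.a * math.exp(-p.c * x_delayed) - p.b * x_now
    if k == "threshold":
        return (1.0 if x_delayed <= 1.0 else 0.0) - p.b * x_now
    if k == "sign":
        return 1.0 if x_delayed <= 0.0 else -1.0
    if k == "wright_reduced":
        return math.exp(_clamp(-x_delayed, -_EXP_CLAMP, _EXP_CLAMP)) - p.b1
    if k == "upper_reduced":
        return -math.exp(_clamp(x_delayed, -_EXP_CLAMP, _EXP_CLAMP)) - x_now - p.b1
    raise ValueError(f"unknown model kind {k!r}")  # pragma: no cover


def make_rhs(model: ModelSpec) -> Callable[[float, float], float]:
    """Specialized rhs closure ``f(x_now, x_delayed)`` for tight loops."""
    k = model.kind
    if k == "hill":
        p, b = model.params.p, model.params.b

        def f(x: float, xd: float) -> float:
            if xd <= 0.0:
                raise DomainError("hill feedback requires a positive delayed state")
            m = _clamp(p * math.log(xd), -_EXP_CLAMP, _EXP_CLAMP)
            if m >= 0.0:
                e = math.exp(-m)
                return e / (1.0 + e) - b * x
            return 1.0 / (1.0 + math.exp(m)) - b * x

        return f
    if k == "sigmoidal":
        kap = model.params.kappa
        return lambda x, xd: -math.tanh(kap * xd)
    if k == "wazewska":
        a, b, c = model.params.a, model.params.b, model.params.c

        def f(x: float, xd: float) -> float:
            if xd <= 0.0:
                raise DomainError("wazewska model requires a positive delayed state")
            return a * math.exp(-c * xd) - b * x

        return f
    if k == "wright_reduced":
        b1 = model.params.b1
        return lambda x, xd: math.exp(_clamp(-xd, -_EXP_CLAMP, _EXP_CLAMP)) - b1
    if k == "upper_reduced":
        b1 = model.params.b1
        return lambda x, xd: -math.exp(_clamp(xd, -_EXP_CLAMP, _EXP_CLAMP)) - x - b1
    return lambda x, xd: rhs(model, x, xd)


def hill_steady_state(b: float, p: float) -> float:
    """Unique positive steady state of the Mackey-Glass equation.

    Solves x * (1 + x**p) = 1/b, whose left side is strictly increasing, by
    bracketed root-finding on the logarithm (stable for steep ``p``).
    """
    if b <= 0:
        raise ValueError("decay rate b must be positive")
    target = -math.log(b)  # log(1/b)

    def g(x: float) -> float:
        lx = math.log(x)
        # log(x * (1 + x^p)) = log x + logaddexp(0, p log x)
        m = p * lx
        if m > 0:
            lse = m + math.log1p(math.exp(-min(m, _EXP_CLAMP)))
        else:
            lse = math.log1p(math.exp(max(m, -_EXP_CLAMP)))
        return lx + lse - target

    lo, hi = 1e-12, max(1.0 / b, 1.0)
    while g(lo) > 0:  # pragma: no cover - b astronomically large
        lo /= 1e6
    return brentq(g, lo, hi, rtol=1e-15, maxiter=200)


def steady_state(model: ModelSpec) -> float | None:
    """Steady state of the model, or None if no steady state exists.

    The threshold model has no steady state for b < 1 (the equilibrium of
    either branch is inconsistent with its own production rule), which is
    exactly its oscillatory regime.
    """
    k = model.kind
    p = model.params
    if k in ("sigmoidal", "sign"):
        return 0.0
    if k == "hill":
        return hill_steady_state(p.b, p.p)
    if k == "wazewska":
        hi = p.a / p.b
        return brentq(lambda x: p.a * math.exp(-p.c * x) - p.b * x, 0.0, hi + 1.0, rtol=1e-15)
    if k == "threshold":
        return 1.0 / p.b if p.b > 1.0 else None
    if k == "wright_reduced":
        return -math.log(p.b1) if p.b1 > 0 else None
    if k == "upper_reduced":
        # u + exp(u) = -b1, strictly increasing left side
        t = -p.b1
        lo = min(t - 1.0, -_EXP_CLAMP)
        hi = max(t, 1.0)
        return brentq(lambda u: u + math.exp(_clamp(u, -_EXP_CLAMP, _EXP_CLAMP)) - t, lo, hi,
                      rtol=1e-15)
    raise ValueError(f"unknown model kind {k!r}")  # pragma: no cover


def _check_branch(branch: str) -> None:
    if branch not in ("lower", "upper"):
        raise ValueError("branch must be 'lower' or 'upper'")


def lift_reduced_state(u: float, p: float, branch: str) -> float:
    """Map a reduced state u back to the full Mackey-Glass state x.

    Lower branch (near the small-b Hopf point): x = 1 + (ln p + u) / p.
    Upper branch (near the b ~ 1 Hopf point):   x = 1 - ln(p)/p + u/p.
    """
    _check_branch(branch)
    if p <= 0:
        raise ValueError("p must be positive")
    if branch == "lower":
        return 1.0 + (math.log(p) + u) / p
    return 1.0 - math.log(p) / p + u / p


def project_full_state(x: float, p: float, branch: str) -> float:
    """Inverse of :func:`lift_reduced_state` (exact round-trip)."""
    _check_branch(branch)
    if p <= 0:
        raise ValueError("p must be positive")
    if branch == "lower":
        return (x - 1.0) * p - math.log(p)
    return (x - 1.0 + math.log(p) / p) * p


def lift_reduced_parameter(b1: float, p: float, branch: str) -> float:
    """Map the reduced control parameter b1 to the full decay rate b.

    Lower branch: b = b1 / p.  Upper branch: b = 1 + (ln p + b1) / p.
    """
    _check_branch(branch)
    if p <= 0:
        raise ValueError("p must be positive")
    if branch == "lower":
        return b1 / p
    return 1.0 + (math.log(p) + b1) / p


def project_full_parameter(b: float, p: float, branch: str) -> float:
    """Inverse of :func:`lift_reduced_parameter`."""
    _check_branch(branch)
    if p <= 0:
        raise ValueError("p must be positive")
    if branch == "lower":
        return b * p
    return (b - 1.0) * p - math.log(p)


# ---------------------------------------------------------------------------
# flat key-value serialization (plain dict / YAML-friendly)

def model_to_dict(model: ModelSpec) -> dict:
    d = {"kind": model.kind, "tau": model.delay}
    for f in fields(model.params):
        d[f.name] = getattr(model.params, f.name)
    return d


def model_from_dict(d: dict) -> ModelSpec:
    d = dict(d)
    kind = d.pop("kind")
    tau = d.pop("tau")
    if kind not in _PARAM_TYPES:
        raise ValueError(f"unknown model kind {kind!r}")
    cls = _PARAM_TYPES[kind]
    names = {f.name for f in fields(cls)}
    extra = set(d) - names
    if extra:
        raise ValueError(f"unexpected parameters for kind {kind!r}: {sorted(extra)}")
    return ModelSpec(kind=kind, params=cls(**d), delay=float(tau))
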
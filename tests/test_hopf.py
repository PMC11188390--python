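import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ddnf
from ddnf import (
    HillParams,
    ModelSpec,
    NoHopfPointError,
    ReducedParams,
    characteristic_residual,
    hill_steady_state,
    hopf_curve,
    hopf_period_approx,
    hopf_point_at_tau,
    integrate,
    lift_reduced_parameter,
    lift_reduced_state,
    lower_branch_approx,
    reduced_hopf,
    sigmoidal_hopf_delay,
    summarize_oscillation,
    upper_branch_approx,
)
from ddnf.models import project_full_parameter

P, TAU = 20.0, 1.8


def test_sigmoidal_hopf_delay():
    assert sigmoidal_hopf_delay(10.0) == pytest.approx(0.15708, abs=1e-5)
    assert sigmoidal_hopf_delay(1e9) < 1e-8
    with pytest.raises(ValueError):
        sigmoidal_hopf_delay(0.0)


@given(kappa=st.floats(1e-3, 1e3))
def test_sigmoidal_hopf_delay_scaling(kappa):
    assert kappa * sigmoidal_hopf_delay(kappa) == pytest.approx(math.pi / 2, rel=1e-12)


def test_hill_steady_state_properties():
    assert hill_steady_state(0.5, 7.0) == pytest.approx(1.0, rel=1e-12)
    x = hill_steady_state(0.05, 20.0)
    assert x * (1 + x**20) == pytest.approx(20.0, rel=1e-10)
    xs = [hill_steady_state(b, 20.0) for b in (0.01, 0.05, 0.2, 0.5, 1.0, 5.0)]
    assert all(a > b for a, b in zip(xs, xs[1:]))  # strictly decreasing in b


def test_characteristic_residual_no_delay_and_zero_root():
    x = hill_steady_state(0.5, 20.0)
    a = 20.0 * x ** 19 / (1 + x**20) ** 2
    # tau -> 0+: the unique real root is lambda = -A - b
    r = characteristic_residual(complex(-a - 0.5, 0.0), 0.5, 20.0, 1e-12)
    assert abs(r) < 1e-8
    # lambda = 0 is never a root: residual = A + b > 0
    r0 = characteristic_residual(0.0 + 0.0j, 0.5, 20.0, 1.8)
    assert r0.real == pytest.approx(a + 0.5, rel=1e-10) and r0.real > 0


def test_hopf_points_at_reference_delay():
    lo = hopf_point_at_tau(TAU, P, "lower")
    up = hopf_point_at_tau(TAU, P, "upper")
    assert lo.b == pytest.approx(0.048, abs=5e-4)
    assert abs(up.b - 1.04) < 0.01
    assert math.pi / 2 < lo.z < up.z < math.pi
    assert lo.b < up.b
    for pt in (lo, up):
        assert abs(characteristic_residual(1j * pt.omega, pt.b, P, TAU)) < 1e-8
        assert pt.omega == pytest.approx(pt.z / TAU)
        # real-part positivity condition for x^p
        assert P * math.cos(pt.z) + 1.0 < 0.0
        assert pt.x_ss == pytest.approx(hill_steady_state(pt.b, P), rel=1e-9)


def test_no_hopf_point_below_boundary_minimum():
    curve = hopf_curve(P, 400)
    tau_min = float(np.min(curve.tau))
    with pytest.raises(NoHopfPointError):
        hopf_point_at_tau(0.5 * tau_min, P, "lower")


def test_hopf_curve_consistency():
    """Interpolating b(tau) along the two monotone arcs of the curve
    reproduces the directly-computed Hopf points at tau = 1.8."""
    curve = hopf_curve(P, 4000)
    assert np.all(curve.tau > 0) and np.all(curve.b > 0)
    split = int(np.argmin(curve.tau))  # tau(z) dips to a minimum between the arcs
    arcs = {
        "lower": (curve.tau[: split + 1][::-1], curve.b[: split + 1][::-1]),
        "upper": (curve.tau[split:], curve.b[split:]),
    }
    for branch, (tau_arc, b_arc) in arcs.items():
        pt = hopf_point_at_tau(TAU, P, branch)
        b_interp = float(np.interp(TAU, tau_arc, b_arc))
        assert b_interp == pytest.approx(pt.b, rel=0.01)


def test_hopf_curve_lower_branch_asymptote():
    """Near z_min = arccos(-1/p), b*tau approaches pi/(2p) (O(1/p) rate)."""
    from ddnf.hopf import _chain_from_z

    z_min = math.acos(-1.0 / P)
    _, b, tau = _chain_from_z(z_min + 1e-3, P)
    assert b * tau == pytest.approx(math.pi / (2 * P), rel=0.10)


def test_lower_branch_approx():
    assert lower_branch_approx(TAU, P) == pytest.approx(0.04363, abs=1e-5)
    numeric = hopf_point_at_tau(TAU, P, "lower").b
    rel = abs(lower_branch_approx(TAU, P) - numeric) / numeric
    assert 0.05 < rel < 0.15  # O(1/p) discrepancy at p = 20


@given(tau=st.floats(0.1, 10.0), p=st.floats(2.0, 500.0))
def test_lower_branch_scaling_identity(tau, p):
    assert lower_branch_approx(tau, p) * p * tau == pytest.approx(math.pi / 2, rel=1e-12)


def test_upper_branch_approx():
    b, z0, x1 = upper_branch_approx(TAU, P)
    assert b == pytest.approx(1.0 + (math.log(P) - 0.4695 - math.exp(0.4695)) / P, abs=1e-4)
    assert abs(b - 1.04) < 0.01
    assert z0 == pytest.approx(2.2463, abs=1e-4)
    assert x1 == pytest.approx(0.4695, abs=1e-4)
    assert math.cos(z0) == pytest.approx(-0.6253, abs=1e-4)
    # numeric and asymptotic Hopf points agree to O(1/p)
    numeric = hopf_point_at_tau(TAU, P, "upper").b
    assert b == pytest.approx(numeric, rel=5e-3)
    # b -> 1 from above-ish as p -> infinity
    b_big, _, _ = upper_branch_approx(TAU, 1e8)
    assert b_big == pytest.approx(1.0, abs=1e-6)


def test_reduced_hopf_values():
    assert reduced_hopf(TAU, "lower") == pytest.approx(math.pi / 3.6, rel=1e-12)
    assert reduced_hopf(TAU, "upper") == pytest.approx(-2.0687, abs=1e-4)
    assert reduced_hopf(1e9, "lower") < 1e-8


@given(tau=st.floats(0.1, 10.0))
def test_reduced_hopf_lifts_reproduce_large_p_approximations(tau):
    """Lifting the reduced Hopf points gives the full-model closed forms exactly."""
    assert lift_reduced_parameter(reduced_hopf(tau, "lower"), P, "lower") == pytest.approx(
        lower_branch_approx(tau, P), rel=1e-13
    )
    b_approx, _, _ = upper_branch_approx(tau, P)
    assert lift_reduced_parameter(reduced_hopf(tau, "upper"), P, "upper") == pytest.approx(
        b_approx, rel=1e-13
    )


def test_hopf_period_approx():
    assert hopf_period_approx(20.0) == pytest.approx(3.8766, abs=1e-4)
    assert round(hopf_period_approx(20.0), 2) == 3.88
    assert hopf_period_approx(1e9) == pytest.approx(4.0, abs=1e-6)
    ps = [5.0, 20.0, 100.0, 1000.0]
    vals = [hopf_period_approx(p) for p in ps]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_oscillations_only_between_the_hopf_points(mackey_glass_run):
    """Sustained oscillation for b inside (b_H2, b_H1), decay outside."""
    for b in (0.06, 0.5):
        _, s = mackey_glass_run(b)
        assert s.sustained, f"expected sustained oscillation at b={b}"
    for b in (0.03, 1.2):
        _, s = mackey_glass_run(b)
        assert not s.sustained, f"expected decay at b={b}"


def test_wright_reduction_matches_full_minima(mackey_glass_run):
    """Near the lower Hopf point the lifted Wright-equation minima track the
    full model; the maxima are allowed to diverge."""
    b = 0.06
    _, full = mackey_glass_run(b)
    b1 = project_full_parameter(b, P, "lower")
    red = ModelSpec("wright_reduced", ReducedParams(b1=b1, p=P), TAU)
    s = summarize_oscillation(integrate(red, t_end=400 * TAU))
    assert lift_reduced_state(s.x_min, P, "lower") == pytest.approx(full.x_min, abs=0.01)


def test_upper_reduction_matches_full_maxima(mackey_glass_run):
    """Near the upper Hopf point the lifted reduced maxima track the full
    model; the minima are allowed to diverge."""
    b = 1.0
    _, full = mackey_glass_run(b)
    b1 = project_full_parameter(b, P, "upper")
    red = ModelSpec("upper_reduced", ReducedParams(b1=b1, p=P), TAU)
    s = summarize_oscillation(integrate(red, t_end=400 * TAU))
    assert lift_reduced_state(s.x_max, P, "upper") == pytest.approx(full.x_max, abs=0.01)


def test_hopf_point_input_validation():
    with pytest.raises(ValueError):
        hopf_point_at_tau(-1.0, P, "lower")
    with pytest.raises(ValueError):
        hopf_point_at_tau(TAU, 0.5, "lower")
    with pytest.raises(ValueError):
        hopf_point_at_tau(TAU, P, "middle")
    with pytest.raises(ValueError):
        upper_branch_approx(-1.0, P)
    with pytest.raises(ValueError):
        hopf_curve(P, 5)
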
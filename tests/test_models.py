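import math

import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

import ddnf
from ddnf.models import (
    DomainError,
    HillParams,
    ModelSpec,
    ReducedParams,
    SigmoidalParams,
    SignParams,
    ThresholdParams,
    WazewskaParams,
    hill_feedback,
    lift_reduced_parameter,
    lift_reduced_state,
    model_from_dict,
    model_to_dict,
    project_full_parameter,
    project_full_state,
    rhs,
    sigmoidal_feedback,
    steady_state,
)


@pytest.mark.parametrize(
    "x,p,expected,tol",
    [
        (1.0, 20.0, 0.5, 0.0),  # symmetry point of the Hill function
        (1e-12, 20.0, 1.0, 1e-12),  # activation limit x -> 0+
        (1.1, 20.0, 1.0 / (1.0 + 1.1**20), 1e-12),  # 1.1^20 = 6.72750
    ],
)
def test_hill_feedback_values(x, p, expected, tol):
    assert hill_feedback(x, p) == pytest.approx(expected, abs=tol)


def test_hill_feedback_heaviside_limit():
    """As p grows, 1/(1+x^p) -> 1 below the threshold and -> 0 above it."""
    below = [1.0 - hill_feedback(0.9, p) for p in (20.0, 100.0, 1000.0)]
    above = [hill_feedback(1.1, p) for p in (20.0, 100.0, 1000.0)]
    assert below[0] > below[1] > below[2]
    assert above[0] > above[1] > above[2]
    assert below[2] < 1e-40 and above[2] < 1e-40
    assert hill_feedback(1.0, 1000.0) == 0.5


def test_hill_feedback_stable_for_steep_exponents():
    v = hill_feedback(2.0, 800.0)
    assert 0.0 <= v <= 1e-100
    assert hill_feedback(0.5, 800.0) == pytest.approx(1.0)
    assert math.isfinite(hill_feedback(35.0, 20.0))


def test_hill_feedback_rejects_nonpositive_state():
    with pytest.raises(DomainError):
        hill_feedback(0.0, 20.0)
    with pytest.raises(DomainError):
        hill_feedback(-1.0, 20.0)


@given(
    x1=st.floats(1e-6, 50.0),
    dx=st.floats(1e-6, 10.0),
    p=st.floats(0.5, 300.0),
)
def test_hill_feedback_strictly_decreasing(x1, dx, p):
    assert hill_feedback(x1, p) >= hill_feedback(x1 + dx, p)


@pytest.mark.parametrize(
    "x,kappa,expected",
    [
        (0.0, 10.0, 0.0),
        (0.4, 10.0, -math.tanh(4.0)),  # -0.999329
        (-0.4, 10.0, math.tanh(4.0)),
    ],
)
def test_sigmoidal_feedback_values(x, kappa, expected):
    assert sigmoidal_feedback(x, kappa) == pytest.approx(expected, abs=1e-12)


@given(x=st.floats(-5.0, 5.0), kappa=st.floats(0.1, 50.0))
def test_sigmoidal_feedback_odd(x, kappa):
    assert sigmoidal_feedback(-x, kappa) == pytest.approx(
        -sigmoidal_feedback(x, kappa), abs=1e-14
    )


def _model(kind, tau=1.8, **kw):
    cls = {
        "hill": HillParams,
        "sigmoidal": SigmoidalParams,
        "wazewska": WazewskaParams,
        "threshold": ThresholdParams,
        "sign": SignParams,
        "wright_reduced": ReducedParams,
        "upper_reduced": ReducedParams,
    }[kind]
    return ModelSpec(kind, cls(**kw), tau)


@pytest.mark.parametrize(
    "model,x_now,x_delayed,expected",
    [
        (_model("hill", p=20.0, b=0.5), 1.0, 1.0, 0.0),  # steady state
        (_model("threshold", b=0.4), 0.5, 1.5, -0.2),  # production off
        (_model("threshold", b=0.4), 0.5, 1.0, 1.0 - 0.2),  # at threshold: on
        (_model("wright_reduced", b1=1.0), 3.7, 0.0, 0.0),  # exp(0) - 1
        (_model("sign"), 0.3, 0.0, 1.0),  # at threshold: production on
        (_model("sign"), 0.3, 0.2, -1.0),
    ],
)
def test_rhs_examples(model, x_now, x_delayed, expected):
    assert rhs(model, x_now, x_delayed) == pytest.approx(expected, abs=1e-14)


def test_upper_reduced_steady_state_consistency():
    """u' = -exp(u_d) - u - b1 vanishes where b1 = -(u + e^u)."""
    u = 0.4695
    b1 = -(u + math.exp(u))
    m = _model("upper_reduced", b1=b1)
    assert rhs(m, u, u) == pytest.approx(0.0, abs=1e-14)
    assert steady_state(m) == pytest.approx(u, abs=1e-12)


@pytest.mark.parametrize(
    "u,p,branch,expected",
    [
        (0.0, 20.0, "lower", 1.0 + math.log(20.0) / 20.0),  # 1.14979
        (0.0, 20.0, "upper", 1.0 - math.log(20.0) / 20.0),  # 0.85021
    ],
)
def test_lift_reduced_state_values(u, p, branch, expected):
    assert lift_reduced_state(u, p, branch) == pytest.approx(expected, rel=1e-14)


@pytest.mark.parametrize(
    "b1,p,branch,expected,tol",
    [
        (1.0, 20.0, "lower", 0.05, 1e-15),
        (-2.0687, 20.0, "upper", 1.0 + (math.log(20.0) - 2.0687) / 20.0, 1e-15),  # 1.04635
        (math.pi / 3.6, 20.0, "lower", math.pi / 72.0, 1e-15),  # 0.043633
    ],
)
def test_lift_reduced_parameter_values(b1, p, branch, expected, tol):
    assert lift_reduced_parameter(b1, p, branch) == pytest.approx(expected, abs=tol)


@given(
    u=st.floats(-10.0, 10.0),
    p=st.sampled_from([5.0, 20.0, 100.0]),
    branch=st.sampled_from(["lower", "upper"]),
)
def test_lift_project_round_trip(u, p, branch):
    x = lift_reduced_state(u, p, branch)
    assert project_full_state(x, p, branch) == pytest.approx(u, abs=1e-9)
    b = lift_reduced_parameter(u, p, branch)
    assert project_full_parameter(b, p, branch) == pytest.approx(u, abs=1e-9)


@pytest.mark.parametrize(
    "bad",
    [
        lambda: SigmoidalParams(kappa=0.0),
        lambda: HillParams(p=-1.0, b=0.1),
        lambda: HillParams(p=20.0, b=-0.1),
        lambda: WazewskaParams(a=1.0, b=0.0, c=1.0),
        lambda: ThresholdParams(b=0.0),
        lambda: ReducedParams(b1=1.0, p=0.0),
        lambda: ModelSpec("hill", HillParams(p=20.0, b=0.1), delay=0.0),
        lambda: ModelSpec("nope", HillParams(p=20.0, b=0.1), delay=1.0),
        lambda: ModelSpec("hill", SigmoidalParams(kappa=1.0), delay=1.0),
    ],
)
def test_construction_validation(bad):
    with pytest.raises((ValueError, TypeError)):
        bad()


def test_steady_states():
    assert steady_state(_model("hill", p=20.0, b=0.5)) == pytest.approx(1.0, rel=1e-12)
    assert steady_state(_model("threshold", b=0.4)) is None
    assert steady_state(_model("threshold", b=2.0)) == pytest.approx(0.5)
    assert steady_state(_model("sigmoidal", kappa=10.0)) == 0.0
    assert steady_state(_model("wright_reduced", b1=1.0)) == pytest.approx(0.0, abs=1e-14)
    xs = steady_state(_model("wazewska", a=2.0, b=0.5, c=2.0))
    assert 2.0 * math.exp(-2.0 * xs) == pytest.approx(0.5 * xs, rel=1e-10)


@pytest.mark.parametrize(
    "model",
    [
        _model("hill", p=20.0, b=0.1),
        _model("sigmoidal", tau=0.4, kappa=10.0),
        _model("wazewska", a=2.0, b=0.5, c=2.0),
        _model("threshold", b=0.4),
        _model("wright_reduced", b1=1.2, p=20.0),
    ],
)
def test_serialization_round_trip(model):
    d = model_to_dict(model)
    assert model_from_dict(d) == model
    assert model_from_dict(yaml.safe_load(yaml.safe_dump(d))) == model


def test_from_dict_rejects_unknown_parameters():
    with pytest.raises(ValueError, match="unexpected"):
        model_from_dict({"kind": "hill", "tau": 1.8, "p": 20.0, "b": 0.1, "kappa": 3.0})


def test_public_api_exports():
    assert ddnf.hill_feedback is hill_feedback
    assert ddnf.__version__
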
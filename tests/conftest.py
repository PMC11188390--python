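import math

import pytest
from hypothesis import HealthCheck, settings

import ddnf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TAU = 1.8
P = 20.0


@pytest.fixture(scope="session")
def mackey_glass_run():
    """Memoized long Mackey-Glass integrations shared across tests."""
    cache: dict = {}

    def run(b, p=P, tau=TAU, t_end_delays=400, steps_per_delay=200, transient=0.5):
        key = (b, p, tau, t_end_delays, steps_per_delay, transient)
        if key not in cache:
            model = ddnf.ModelSpec("hill", ddnf.HillParams(p=p, b=b), tau)
            traj = ddnf.integrate(
                model, t_end=t_end_delays * tau, steps_per_delay=steps_per_delay
            )
            cache[key] = (traj, ddnf.summarize_oscillation(traj, transient))
        return cache[key]

    return run


@pytest.fixture(scope="session")
def sigmoidal_traj():
    """Sawtooth-regime sigmoidal run: kappa=10, tau=0.4 (> tau0 = 0.157)."""
    model = ddnf.ModelSpec("sigmoidal", ddnf.SigmoidalParams(kappa=10.0), 0.4)
    return ddnf.integrate(model, t_end=100 * 0.4)


@pytest.fixture(scope="session")
def sigmoidal_summary(sigmoidal_traj):
    return ddnf.summarize_oscillation(sigmoidal_traj)


SAWTOOTH_PEAK = 0.4 - math.log(2.0) / 10.0  # tau - ln(2)/kappa at kappa=10, tau=0.4
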
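"""Bifurcation-diagram sweeps, analytic overlays, diagram IO, and test fixtures.

A sweep integrates the model over a grid of one parameter (``b`` or ``tau``),
summarizes the post-transient oscillation at each point, and attaches the
requested closed-form overlays (threshold-limit extrema and period, sawtooth
extrema, local Hopf amplitude, lifted reduced-model predictions).  Diagrams
are stored in a long-format table (param, quantity, value, source) so numeric
results and analytic overlays share one schema.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import limits
from .engine import (
    HistorySpec,
    OscillationSummary,
    Trajectory,
    integrate,
    summarize_oscillation,
)
from .models import ModelSpec, lift_reduced_state, model_from_dict, model_to_dict

__all__ = [
    "SweepConfig",
    "BifurcationDiagram",
    "sweep",
    "generate_fixture",
    "write_diagram",
    "read_diagram",
    "DiagramParseError",
]

logger = logging.getLogger(__name__)

_QUANTITIES = ("x_min", "x_max", "period", "period_over_tau")


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a one-parameter bifurcation sweep.

    ``t_end_delays`` sets the integration horizon in units of the delay; use
    several hundred near Hopf points (critical slowing down) and ~100
    elsewhere.  ``warm_start`` reuses the previous grid point's final state as
    the next constant history, tracking the attractor along the sweep.
    """

    model: ModelSpec
    sweep_param: str  # "b" or "tau"
    grid: tuple
    steps_per_delay: int = 200
    t_end_delays: float = 100.0
    transient_fraction: float = 0.5
    warm_start: bool = True
    overlays: tuple = ()

    def __post_init__(self) -> None:
        if self.sweep_param not in ("b", "tau"):
            raise ValueError("sweep_param must be 'b' or 'tau'")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be nonempty and strictly increasing")
        if self.sweep_param == "b" and not hasattr(self.model.params, "b"):
            raise ValueError(f"model kind {self.model.kind!r} has no parameter 'b'")

    def model_at(self, value: float) -> ModelSpec:
        d = model_to_dict(self.model)
        d[self.sweep_param] = float(value)
        return model_from_dict(d)

    @staticmethod
    def from_dict(d: dict) -> "SweepConfig":
        d = dict(d)
        model = model_from_dict(d.pop("model"))
        d["grid"] = tuple(float(v) for v in d["grid"])
        d["overlays"] = tuple(d.get("overlays", ()))
        return SweepConfig(model=model, **d)

    def to_dict(self) -> dict:
        return {
            "model": model_to_dict(self.model),
            "sweep_param": self.sweep_param,
            "grid": list(self.grid),
            "steps_per_delay": self.steps_per_delay,
            "t_end_delays": self.t_end_delays,
            "transient_fraction": self.transient_fraction,
            "warm_start": self.warm_start,
            "overlays": list(self.overlays),
        }


@dataclass
class BifurcationDiagram:
    """Per-parameter oscillation summaries plus named analytic overlays.

    ``data`` is the canonical long-format table with columns
    (param, quantity, value, source); ``source`` is "numeric" for simulated
    values, "steady" markers where no sustained oscillation was found, and an
    overlay name otherwise.
    """

    sweep_param: str
    data: pd.DataFrame
    summaries: list = field(default_factory=list)

    def overlay_sources(self) -> list[str]:
        return sorted(set(self.data["source"]) - {"numeric", "steady"})


def _overlay_rows(name: str, config: SweepConfig, grid: np.ndarray) -> list[tuple]:
    model = config.model
    tau = model.delay
    rows: list[tuple] = []
    if name == "threshold_limit":
        for v in grid:
            b = v if config.sweep_param == "b" else model.params.b
            t = v if config.sweep_param == "tau" else tau
            if not 0 < b < 1:
                continue
            cyc = limits.threshold_cycle(b, t)
            rows += [
                (v, "x_min", cyc.x_min, "threshold_xmin"),
                (v, "x_max", cyc.x_max, "threshold_xmax"),
                (v, "period", cyc.period, "threshold_period"),
                (v, "period_over_tau", cyc.period / t, "threshold_period"),
            ]
    elif name == "sawtooth":
        kappa = model.params.kappa
        for v in grid:
            t = v if config.sweep_param == "tau" else tau
            ext = t - math.log(2.0) / kappa
            rows += [
                (v, "x_min", -ext, "sawtooth_extrema"),
                (v, "x_max", ext, "sawtooth_extrema"),
                (v, "period", 4.0 * t, "sawtooth_period"),
                (v, "period_over_tau", 4.0, "sawtooth_period"),
            ]
    elif name == "hopf_amplitude":
        kappa = model.params.kappa
        for v in grid:
            t = v if config.sweep_param == "tau" else tau
            # the local law gives the amplitude of kappa*x; rescale to x
            amp, _valid = limits.hopf_local_amplitude(t, kappa)
            amp /= kappa
            rows += [
                (v, "x_min", -amp, "hopf_amplitude"),
                (v, "x_max", amp, "hopf_amplitude"),
            ]
    elif name in ("reduced_lower", "reduced_upper"):
        rows += _reduced_overlay_rows(name, config, grid)
    else:
        raise ValueError(f"unknown overlay {name!r}")
    return rows


def _reduced_overlay_rows(name: str, config: SweepConfig, grid: np.ndarray) -> list[tuple]:
    """Integrate the reduced equation per grid point and lift its extrema."""
    from .models import ModelSpec as MS
    from .models import ReducedParams, project_full_parameter

    branch = "lower" if name == "reduced_lower" else "upper"
    kind = "wright_reduced" if branch == "lower" else "upper_reduced"
    model = config.model
    p = model.params.p
    tau = model.delay
    rows: list[tuple] = []
    for v in grid:
        b = v if config.sweep_param == "b" else model.params.b
        t = v if config.sweep_param == "tau" else tau
        b1 = project_full_parameter(b, p, branch)
        reduced = MS(kind=kind, params=ReducedParams(b1=b1, p=p), delay=t)
        traj = integrate(
            reduced,
            t_end=config.t_end_delays * t,
            steps_per_delay=config.steps_per_delay,
        )
        summ = summarize_oscillation(traj, config.transient_fraction)
        if not summ.sustained:
            continue
        rows += [
            (v, "x_min", lift_reduced_state(summ.x_min, p, branch), name),
            (v, "x_max", lift_reduced_state(summ.x_max, p, branch), name),
            (v, "period", summ.period, name),
            (v, "period_over_tau", summ.period_in_delay_units, name),
        ]
    return rows


def sweep(config: SweepConfig) -> BifurcationDiagram:
    """Run a bifurcation sweep and attach the requested analytic overlays.

    Each grid point is integrated from a perturbed steady state (or, with
    ``warm_start``, from a constant history at the previous point's final
    state) and summarized.  Integration failures at single points are logged
    and recorded as missing; the sweep continues.
    """
    grid = np.asarray(config.grid, dtype=float)
    rows: list[tuple] = []
    summaries: list[OscillationSummary | None] = []
    prev_final: float | None = None
    for v in grid:
        model = config.model_at(v)
        history = None
        if config.warm_start and prev_final is not None:
            history = HistorySpec.constant(prev_final)
        try:
            traj = integrate(
                model,
                history=history,
                t_end=config.t_end_delays * model.delay,
                steps_per_delay=config.steps_per_delay,
            )
            summ = summarize_oscillation(traj, config.transient_fraction)
        except Exception as exc:  # per-point failures do not abort the sweep
            logger.warning("sweep point %s = %g failed: %s", config.sweep_param, v, exc)
            summaries.append(None)
            continue
        prev_final = float(traj.x[-1])
        summaries.append(summ)
        if summ.sustained:
            logger.info(
                "%s = %g: period = %.6g (converged=%s)",
                config.sweep_param, v, summ.period, summ.converged,
            )
            rows += [
                (v, "x_min", summ.x_min, "numeric"),
                (v, "x_max", summ.x_max, "numeric"),
                (v, "period", summ.period, "numeric"),
                (v, "period_over_tau", summ.period_in_delay_units, "numeric"),
            ]
        else:
            logger.info("%s = %g: no sustained oscillation", config.sweep_param, v)
            rows.append((v, "x_max", summ.x_max, "steady"))
    for name in config.overlays:
        rows += _overlay_rows(name, config, grid)
    data = pd.DataFrame(rows, columns=["param", "quantity", "value", "source"])
    return BifurcationDiagram(sweep_param=config.sweep_param, data=data, summaries=summaries)


class DiagramParseError(ValueError):
    """Malformed diagram file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


def write_diagram(diagram: BifurcationDiagram, path, fmt: str | None = None) -> None:
    """Write a diagram losslessly as long-format CSV or JSON records."""
    fmt = fmt or ("json" if str(path).endswith(".json") else "csv")
    df = diagram.data
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# sweep_param: {diagram.sweep_param}\n")
            fh.write("param,quantity,value,source\n")
            for row in df.itertuples(index=False):
                fh.write(f"{row.param!r},{row.quantity},{row.value!r},{row.source}\n")
    elif fmt == "json":
        import json

        payload = {
            "sweep_param": diagram.sweep_param,
            "rows": [
                {"param": r.param, "quantity": r.quantity, "value": r.value, "source": r.source}
                for r in df.itertuples(index=False)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_diagram(path, fmt: str | None = None) -> BifurcationDiagram:
    """Read a diagram written by :func:`write_diagram` (bit-identical values)."""
    fmt = fmt or ("json" if str(path).endswith(".json") else "csv")
    if fmt == "json":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["rows"], columns=["param", "quantity", "value", "source"])
        if len(df):
            df["param"] = df["param"].astype(float)
            df["value"] = df["value"].astype(float)
        return BifurcationDiagram(sweep_param=payload["sweep_param"], data=df)

    rows = []
    sweep_param = "b"
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("#"):
        sweep_param = lines[0].split(":", 1)[1].strip()
        start = 1
    if start >= len(lines) or lines[start].strip() != "param,quantity,value,source":
        raise DiagramParseError("missing 'param,quantity,value,source' header", start + 1)
    for ln, line in enumerate(lines[start + 1 :], start=start + 2):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise DiagramParseError(f"expected 4 fields, got {len(parts)}", ln)
        try:
            rows.append((float(parts[0]), parts[1], float(parts[2]), parts[3]))
        except ValueError:
            raise DiagramParseError(f"non-numeric value in {line!r}", ln) from None
    df = pd.DataFrame(rows, columns=["param", "quantity", "value", "source"])
    return BifurcationDiagram(sweep_param=sweep_param, data=df)


# ---------------------------------------------------------------------------
# synthetic trajectory fixtures with known period/extrema


def generate_fixture(
    kind: str,
    period: float = 5.0,
    amplitude: float = 0.3,
    offset: float = 1.0,
    decay: float = 0.5,
    tau: float = 1.0,
    noise_amplitude: float = 0.0,
    seed: int | None = None,
    t_end: float | None = None,
    samples_per_unit: int = 50,
) -> tuple[Trajectory, dict]:
    """Deterministic synthetic trajectory of known period and extrema.

    Kinds: ``sine`` (offset + amplitude*sin), ``damped`` (exponentially
    decaying cosine: no sustained oscillation), ``sawtooth`` (the 4*tau
    outer solution), ``square`` (alternating plateaus).  Returns the
    trajectory together with a dict of its true period and extrema.
    """
    if kind not in ("sine", "damped", "sawtooth", "square"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    if kind == "sawtooth":
        period = 4.0 * tau
    if t_end is None:
        t_end = 12.0 * period if kind != "damped" else max(12.0 * period, 30.0 / decay)
    h = 1.0 / samples_per_unit
    n = int(round((t_end + tau) / h))
    t = -tau + h * np.arange(n + 1)
    w = 2.0 * math.pi / period
    if kind == "sine":
        x = offset + amplitude * np.sin(w * t)
        d = amplitude * w * np.cos(w * t)
        truth = {"period": period, "x_min": offset - amplitude, "x_max": offset + amplitude}
    elif kind == "damped":
        env = np.exp(-decay * np.clip(t, 0.0, None))
        x = offset + amplitude * env * np.cos(w * t)
        d = amplitude * env * (-decay * np.where(t > 0, 1.0, 0.0) * np.cos(w * t) - w * np.sin(w * t))
        truth = {"period": None, "x_min": offset, "x_max": offset}
    elif kind == "sawtooth":
        x = limits.sawtooth_outer(t, tau)
        s = np.mod(t, 4.0 * tau)
        d = np.where(s <= tau, 1.0, np.where(s <= 3.0 * tau, -1.0, 1.0))
        truth = {"period": period, "x_min": -tau, "x_max": tau}
    else:  # square
        x = offset + amplitude * np.sign(np.sin(w * t) + 1e-300)
        d = np.zeros_like(t)
        truth = {"period": period, "x_min": offset - amplitude, "x_max": offset + amplitude}
    if noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_amplitude, size=x.shape)
    traj = Trajectory(t=t, x=x, d_out=d.copy(), d_in=d.copy(), delay=tau, step=h)
    return traj, truth
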
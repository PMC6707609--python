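"""Time-domain integration of the parallel memristor circuit.

Because the drive is an ideal voltage source, the two memristor state
equations decouple: the thermistor temperature and the doped-layer extension
each see only the imposed voltage, never each other.  The engine integrates
whichever states are active with an adaptive embedded Runge-Kutta 4(5)
scheme (SciPy's ``RK45``), interpolates the dense solution onto a uniform
grid, and evaluates every branch current on that grid.  All loop features
downstream are computed from the sampled trace, never from raw solver steps.

A classical fixed-step RK4 integrator (`oracle_fixed_step`) of the same
equations is provided purely as an independent numerical cross-check for
tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import (
    CircuitConfig,
    TangentialState,
    TransversalState,
    tangential_conductance,
    tangential_state_derivative,
    transversal_conductance,
    transversal_state_derivative,
)
from .stimulus import Stimulus

__all__ = [
    "SolverOptions",
    "SimulationTrace",
    "SolverError",
    "simulate",
    "oracle_fixed_step",
    "write_trace",
    "read_trace",
]

TRACE_COLUMNS = [
    "t_s",
    "v_V",
    "i_tang_A",
    "i_tran_A",
    "i_c_A",
    "i_total_A",
    "T_K",
    "x",
    "g_tang_S",
    "g_tran_S",
]


class SolverError(RuntimeError):
    """Adaptive integration failed; carries the last accepted time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last accepted t = {last_time:.6g} s)")
        self.last_time = last_time


@dataclass(frozen=True)
class SolverOptions:
    """Integration tolerances and output sampling density."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    samples_per_period: int = 4000

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.samples_per_period < 1000:
            raise ValueError("samples_per_period must be >= 1000")


@dataclass
class SimulationTrace:
    """Uniformly sampled voltages, currents, states and memductances.

    Inactive branch currents are stored as exact zeros; inactive states and
    memductances as NaN.  ``t`` spans ``n_periods`` full periods with
    ``samples_per_period`` intervals per period plus the final endpoint.
    """

    t: np.ndarray
    v: np.ndarray
    i_tang: np.ndarray
    i_tran: np.ndarray
    i_c: np.ndarray
    i_total: np.ndarray
    temperature: np.ndarray
    x: np.ndarray
    g_tang: np.ndarray
    g_tran: np.ndarray
    samples_per_period: int
    n_periods: int
    metadata: dict = field(default_factory=dict)

    @property
    def period(self) -> float:
        return (self.t[-1] - self.t[0]) / self.n_periods

    @property
    def has_tangential(self) -> bool:
        return bool(np.isfinite(self.g_tang).all())

    @property
    def has_transversal(self) -> bool:
        return bool(np.isfinite(self.g_tran).all())

    def period_slice(self, period_index: int) -> slice:
        """Index slice of one full period, inclusive of both boundary samples."""
        if not 0 <= period_index < self.n_periods:
            raise IndexError(
                f"period_index {period_index} outside 0..{self.n_periods - 1}"
            )
        start = period_index * self.samples_per_period
        return slice(start, start + self.samples_per_period + 1)


def _make_rhs(config: CircuitConfig, stimulus: Stimulus):
    """Build the state vector layout and its derivative function.

    Layout: temperature first (if active), then x.  The transversal rate is
    clamped at the state boundaries by zeroing outward-pushing derivatives;
    x is clipped into [0, 1] before the memristance is evaluated so small
    solver overshoots cannot leave the model's domain.
    """
    tang_on = config.include_tangential
    tran_on = config.include_transversal
    p_tang = config.tangential_params
    p_tran = config.transversal_params

    def rhs(t, y):
        v = stimulus.amplitude * math.sin(2.0 * math.pi * stimulus.frequency * t)
        v += stimulus.dc_offset
        out = []
        k = 0
        if tang_on:
            out.append(tangential_state_derivative(y[k], v, p_tang))
            k += 1
        if tran_on:
            x = min(max(y[k], 0.0), 1.0)
            out.append(transversal_state_derivative(x, v, p_tran))
        return out

    y0 = []
    if tang_on:
        y0.append(config.initial_tangential_state.temperature)
    if tran_on:
        y0.append(config.initial_transversal_state.x)
    return rhs, y0


def _assemble_trace(
    t: np.ndarray,
    temperature: np.ndarray | None,
    x: np.ndarray | None,
    config: CircuitConfig,
    stimulus: Stimulus,
    samples_per_period: int,
    metadata: dict,
) -> SimulationTrace:
    v = stimulus.voltage_at(t)
    dvdt = stimulus.dvdt_at(t)
    nan = np.full_like(t, np.nan)
    zero = np.zeros_like(t)

    if config.include_tangential:
        assert temperature is not None
        g_tang = 1.0 / (
            config.tangential_params.r0
            * np.exp(
                config.tangential_params.beta
                * (1.0 / temperature - 1.0 / config.tangential_params.t0)
            )
        )
        i_tang = v * g_tang
    else:
        temperature, g_tang, i_tang = nan, nan, zero

    if config.include_transversal:
        assert x is not None
        x = np.clip(x, 0.0, 1.0)
        m = (
            config.transversal_params.r_on * x
            + config.transversal_params.r_off * (1.0 - x)
        )
        g_tran = 1.0 / m
        i_tran = v / m
    else:
        x, g_tran, i_tran = nan, nan, zero

    i_c = config.capacitance * dvdt
    return SimulationTrace(
        t=t,
        v=v,
        i_tang=i_tang,
        i_tran=i_tran,
        i_c=i_c,
        i_total=i_tang + i_tran + i_c,
        temperature=temperature,
        x=x,
        g_tang=g_tang,
        g_tran=g_tran,
        samples_per_period=samples_per_period,
        n_periods=stimulus.n_periods,
        metadata=metadata,
    )


def simulate(
    config: CircuitConfig,
    stimulus: Stimulus,
    options: SolverOptions | None = None,
) -> SimulationTrace:
    """Integrate the circuit over ``stimulus.n_periods`` periods.

    Returns a :class:`SimulationTrace` sampled on a uniform grid of
    ``samples_per_period`` intervals per period.
    """
    options = options or SolverOptions()
    rhs, y0 = _make_rhs(config, stimulus)
    n_samples = stimulus.n_periods * options.samples_per_period + 1
    t_grid = np.linspace(0.0, stimulus.duration, n_samples)

    metadata = {
        "config": _config_dict(config),
        "stimulus": asdict(stimulus),
        "solver_options": asdict(options),
    }

    if not y0:
        return _assemble_trace(
            t_grid, None, None, config, stimulus, options.samples_per_period, metadata
        )

    sol = solve_ivp(
        rhs,
        (0.0, stimulus.duration),
        y0,
        method="RK45",
        dense_output=True,
        rtol=options.rel_tol,
        atol=options.abs_tol,
        max_step=stimulus.period / 20.0,
    )
    if not sol.success:
        raise SolverError(sol.message, float(sol.t[-1]))

    states = sol.sol(t_grid)
    k = 0
    temperature = None
    x = None
    if config.include_tangential:
        temperature = states[k]
        k += 1
    if config.include_transversal:
        x = states[k]
    return _assemble_trace(
        t_grid, temperature, x, config, stimulus, options.samples_per_period, metadata
    )


def oracle_fixed_step(
    config: CircuitConfig,
    stimulus: Stimulus,
    n_steps_per_period: int,
    store_per_period: int = 4000,
) -> SimulationTrace:
    """Classical fixed-step 4th-order integration of the same equations.

    Test oracle only: deliberately independent of SciPy's adaptive path.
    States are stored at ``store_per_period`` uniformly spaced grid points
    per period, which must divide ``n_steps_per_period``.
    """
    if n_steps_per_period < 10_000:
        raise ValueError("n_steps_per_period must be >= 1e4")
    if n_steps_per_period % store_per_period:
        raise ValueError("store_per_period must divide n_steps_per_period")
    rhs, y0 = _make_rhs(config, stimulus)
    metadata = {
        "config": _config_dict(config),
        "stimulus": asdict(stimulus),
        "solver_options": {"oracle_rk4_steps_per_period": n_steps_per_period},
    }
    n_store = stimulus.n_periods * store_per_period + 1
    t_grid = np.linspace(0.0, stimulus.duration, n_store)
    if not y0:
        return _assemble_trace(
            t_grid, None, None, config, stimulus, store_per_period, metadata
        )

    h = stimulus.period / n_steps_per_period
    decim = n_steps_per_period // store_per_period
    n_steps = stimulus.n_periods * n_steps_per_period
    y = list(y0)
    dim = len(y)
    stored = np.empty((dim, n_store))
    stored[:, 0] = y
    t = 0.0
    for step in range(n_steps):
        k1 = rhs(t, y)
        y2 = [y[j] + 0.5 * h * k1[j] for j in range(dim)]
        k2 = rhs(t + 0.5 * h, y2)
        y3 = [y[j] + 0.5 * h * k2[j] for j in range(dim)]
        k3 = rhs(t + 0.5 * h, y3)
        y4 = [y[j] + h * k3[j] for j in range(dim)]
        k4 = rhs(t + h, y4)
        y = [
            y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            for j in range(dim)
        ]
        t = (step + 1) * h
        if (step + 1) % decim == 0:
            stored[:, (step + 1) // decim] = y

    k = 0
    temperature = None
    x = None
    if config.include_tangential:
        temperature = stored[k]
        k += 1
    if config.include_transversal:
        x = stored[k]
    return _assemble_trace(
        t_grid, temperature, x, config, stimulus, store_per_period, metadata
    )


def _config_dict(config: CircuitConfig) -> dict:
    return {
        "include_tangential": config.include_tangential,
        "include_transversal": config.include_transversal,
        "capacitance": config.capacitance,
        "tangential_params": asdict(config.tangential_params),
        "transversal_params": asdict(config.transversal_params),
        "initial_tangential_state": asdict(config.initial_tangential_state),
        "initial_transversal_state": asdict(config.initial_transversal_state),
    }


def write_trace(trace: SimulationTrace, path: str | Path) -> None:
    """Write a trace as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": trace.t,
            "v_V": trace.v,
            "i_tang_A": trace.i_tang,
            "i_tran_A": trace.i_tran,
            "i_c_A": trace.i_c,
            "i_total_A": trace.i_total,
            "T_K": trace.temperature,
            "x": trace.x,
            "g_tang_S": trace.g_tang,
            "g_tran_S": trace.g_tran,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = dict(trace.metadata)
    sidecar["samples_per_period"] = trace.samples_per_period
    sidecar["n_periods"] = trace.n_periods
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> SimulationTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    metadata: dict = {}
    if sidecar_path.exists():
        metadata = json.loads(sidecar_path.read_text())
    spp = int(metadata.pop("samples_per_period", len(df) - 1))
    n_periods = int(metadata.pop("n_periods", 1))
    return SimulationTrace(
        t=df["t_s"].to_numpy(),
        v=df["v_V"].to_numpy(),
        i_tang=df["i_tang_A"].to_numpy(),
        i_tran=df["i_tran_A"].to_numpy(),
        i_c=df["i_c_A"].to_numpy(),
        i_total=df["i_total_A"].to_numpy(),
        temperature=df["T_K"].to_numpy(),
        x=df["x"].to_numpy(),
        g_tang=df["g_tang_S"].to_numpy(),
        g_tran=df["g_tran_S"].to_numpy(),
        samples_per_period=spp,
        n_periods=n_periods,
        metadata=metadata,
    )
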
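"""Constitutive relations of the two memristor models and the parallel circuit.

Two memristor models are implemented:

* a *tangential* memristor — a self-heating NTC thermistor whose conductance
  ``G(T) = 1 / (R0 * exp(beta * (1/T - 1/T0)))`` increases with device
  temperature ``T``; the temperature obeys a lumped heat balance between
  Joule heating ``G(T) v**2`` and Newtonian dissipation towards ambient;
* a *transversal* memristor — the linear-drift HP titanium-dioxide model,
  whose memristance ``M(x) = R_on x + R_off (1 - x)`` interpolates between
  the fully doped and undoped limits as the normalized doped-layer extension
  ``x`` drifts with the charge passed through the device.  The drift rate is
  scaled by a dimensionless slowdown factor so the state stays away from its
  boundaries under volt-scale, sub-hertz sinusoidal drive.

Both can be placed in parallel with each other and with an ideal constant
capacitance; the branch currents simply add.  All quantities are SI
(Ω, S, F, V, A, K, s); presentation units (kΩ, μF, μS) live at the CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "TangentialModelParams",
    "TangentialState",
    "TransversalModelParams",
    "TransversalState",
    "CircuitConfig",
    "AdmittancePoint",
    "tangential_conductance",
    "tangential_state_derivative",
    "transversal_memristance",
    "transversal_conductance",
    "transversal_state_derivative",
    "capacitor_current",
    "total_current",
    "circuit_admittance",
]


@dataclass(frozen=True)
class TangentialModelParams:
    """NTC-thermistor memristor constants.

    Parameters
    ----------
    r0 : float
        Resistance at the reference (ambient) temperature, Ω.
    t0 : float
        Reference/ambient temperature, K.
    beta : float
        Material-specific exponential constant, K.
    delta : float
        Dissipation constant towards ambient, W/K.
    heat_capacity : float
        Lumped heat capacitance of the device, J/K.
    """

    r0: float = 3890.0
    t0: float = 300.0
    beta: float = 5.0e5
    delta: float = 0.1
    heat_capacity: float = 0.14

    def __post_init__(self) -> None:
        for name in ("r0", "t0", "beta", "delta", "heat_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TangentialState:
    """Device temperature of the thermistor memristor, K."""

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be strictly positive")


@dataclass(frozen=True)
class TransversalModelParams:
    """Linear-drift HP memristor constants.

    ``slowdown`` is a dimensionless factor on the state equation; without it
    the doped-layer extension saturates almost instantly at the drive levels
    used here.  ``mobility = 0`` freezes the state (a plain resistor), which
    is useful for closed-form checks.
    """

    r_on: float = 100.0
    r_off: float = 16000.0
    thickness: float = 1.0e-8
    mobility: float = 1.0e-14
    slowdown: float = 5.0e-4

    def __post_init__(self) -> None:
        if not 0 < self.r_on < self.r_off:
            raise ValueError("need 0 < r_on < r_off")
        if self.thickness <= 0 or self.mobility < 0 or self.slowdown <= 0:
            raise ValueError("thickness and slowdown must be positive, mobility >= 0")


@dataclass(frozen=True)
class TransversalState:
    """Normalized doped-region extension, dimensionless in [0, 1]."""

    x: float = 0.76

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x must lie in [0, 1]")


@dataclass(frozen=True)
class CircuitConfig:
    """Parallel circuit composition: which branches exist and their parameters."""

    include_tangential: bool = True
    include_transversal: bool = True
    capacitance: float = 0.0
    tangential_params: TangentialModelParams = field(default_factory=TangentialModelParams)
    transversal_params: TransversalModelParams = field(default_factory=TransversalModelParams)
    initial_tangential_state: TangentialState = field(default_factory=TangentialState)
    initial_transversal_state: TransversalState = field(default_factory=TransversalState)

    def __post_init__(self) -> None:
        if self.capacitance < 0:
            raise ValueError("capacitance must be >= 0")
        if not (self.include_tangential or self.include_transversal or self.capacitance > 0):
            raise ValueError("circuit must contain at least one branch")

    @property
    def n_memristors(self) -> int:
        return int(self.include_tangential) + int(self.include_transversal)


@dataclass(frozen=True)
class AdmittancePoint:
    """Small-signal admittance Y = G + jB of the parallel circuit at a state."""

    conductance_real: float
    susceptance: float
    angular_frequency: float


def tangential_conductance(temperature: float, params: TangentialModelParams) -> float:
    """Temperature-dependent conductance of the NTC memristor, S.

    ``G(T) = [r0 * exp(beta * (1/T - 1/t0))]^-1``; strictly increasing in T.
    """
    if temperature <= 0:
        raise ValueError("temperature must be strictly positive")
    return 1.0 / (params.r0 * math.exp(params.beta * (1.0 / temperature - 1.0 / params.t0)))


def tangential_state_derivative(
    temperature: float, voltage: float, params: TangentialModelParams
) -> float:
    """Rate of change of device temperature, K/s.

    Newtonian cooling towards ambient plus Joule self-heating; even in the
    voltage, so the thermal trajectory is invariant under a sign flip of the
    drive.
    """
    cooling = params.delta / params.heat_capacity * (params.t0 - temperature)
    heating = tangential_conductance(temperature, params) / params.heat_capacity * voltage**2
    return cooling + heating


def transversal_memristance(x: float, params: TransversalModelParams) -> float:
    """Memristance M(x) = r_on*x + r_off*(1-x), Ω; affine and decreasing in x."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    return params.r_on * x + params.r_off * (1.0 - x)


def transversal_conductance(x: float, params: TransversalModelParams) -> float:
    """Memductance G_tran(x) = 1/M(x), S."""
    return 1.0 / transversal_memristance(x, params)


def transversal_state_derivative(
    x: float, voltage: float, params: TransversalModelParams
) -> float:
    """Rate of change of the doped-layer extension, 1/s.

    Linear dopant drift proportional to branch current, scaled by the
    slowdown factor.  At the state boundaries an outward-pushing rate is
    replaced by zero (hard clamp); inward rates pass through.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    current = voltage / transversal_memristance(x, params)
    rate = params.mobility * params.r_on / params.thickness**2 * current * params.slowdown
    if (x >= 1.0 and rate > 0.0) or (x <= 0.0 and rate < 0.0):
        return 0.0
    return rate


def capacitor_current(dv_dt: float, capacitance: float) -> float:
    """Displacement current i_C = C dv/dt, A."""
    if capacitance < 0:
        raise ValueError("capacitance must be >= 0")
    return capacitance * dv_dt


def total_current(
    voltage: float,
    dv_dt: float,
    tangential_state: TangentialState | None,
    transversal_state: TransversalState | None,
    config: CircuitConfig,
) -> tuple[float, float, float, float]:
    """Branch currents and their sum for the parallel circuit.

    Returns ``(i_tang, i_tran, i_c, i_total)``; inactive branches contribute
    exactly zero.
    """
    i_tang = 0.0
    i_tran = 0.0
    if config.include_tangential:
        if tangential_state is None:
            raise ValueError("tangential branch active but no state given")
        i_tang = voltage * tangential_conductance(
            tangential_state.temperature, config.tangential_params
        )
    if config.include_transversal:
        if transversal_state is None:
            raise ValueError("transversal branch active but no state given")
        i_tran = voltage * transversal_conductance(
            transversal_state.x, config.transversal_params
        )
    i_c = capacitor_current(dv_dt, config.capacitance)
    return i_tang, i_tran, i_c, i_tang + i_tran + i_c


def circuit_admittance(
    x: float | None,
    temperature: float | None,
    frequency: float,
    config: CircuitConfig,
) -> AdmittancePoint:
    """Small-signal admittance around an operating state.

    The real part is the sum of the active branch memductances; the imaginary
    part is the capacitive susceptance ``B = 2*pi*f*C``.
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    g = 0.0
    if config.include_tangential:
        if temperature is None:
            raise ValueError("tangential branch active but no temperature given")
        g += tangential_conductance(temperature, config.tangential_params)
    if config.include_transversal:
        if x is None:
            raise ValueError("transversal branch active but no x given")
        g += transversal_conductance(x, config.transversal_params)
    omega = 2.0 * math.pi * frequency
    return AdmittancePoint(
        conductance_real=g,
        susceptance=omega * config.capacitance,
        angular_frequency=omega,
    )
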
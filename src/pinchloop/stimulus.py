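"""Ideal sinusoidal voltage source with analytic time derivative.

The analytic derivative is needed for the capacitor branch: the source is
ideal, so the displacement current is C dv/dt evaluated exactly rather than
by numerical differentiation.  Phase convention: the waveform is a sine
starting at zero, so a positive-amplitude run begins with its positive half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Stimulus"]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class Stimulus:
    """Sinusoid ``v(t) = amplitude * sin(2*pi*frequency*t) + dc_offset``.

    ``amplitude`` may be negative (sign flip of the drive); ``n_periods`` is
    the number of full periods a simulation covers.
    """

    amplitude: float = 4.5
    frequency: float = 0.025
    dc_offset: float = 0.0
    n_periods: int = 2

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")

    @property
    def period(self) -> float:
        """Duration of one full period, s."""
        return 1.0 / self.frequency

    @property
    def duration(self) -> float:
        """Total simulated time span, s."""
        return self.n_periods * self.period

    def voltage_at(self, t):
        """Source voltage at time(s) ``t``, V."""
        return self.amplitude * np.sin(_TWO_PI * self.frequency * np.asarray(t)) + self.dc_offset

    def dvdt_at(self, t):
        """Analytic time derivative of the source voltage, V/s."""
        return (
            _TWO_PI
            * self.frequency
            * self.amplitude
            * np.cos(_TWO_PI * self.frequency * np.asarray(t))
        )


def voltage_at(stimulus: Stimulus, t):
    """Functional alias for :meth:`Stimulus.voltage_at`."""
    return stimulus.voltage_at(t)


def dvdt_at(stimulus: Stimulus, t):
    """Functional alias for :meth:`Stimulus.dvdt_at`."""
    return stimulus.dvdt_at(t)
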
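"""Shared fixtures: canonical simulation traces, reused across test modules.

All traces use the canonical drive (4.5 V, 0.025 Hz, two periods) unless a
test builds its own; they are session-scoped because the forward simulations
are deterministic.
"""

from dataclasses import replace

import numpy as np
import pytest

from pinchloop import CircuitConfig, SimulationTrace, Stimulus, simulate

TANG_ONLY = CircuitConfig(include_tangential=True, include_transversal=False)
TRAN_ONLY = CircuitConfig(include_tangential=False, include_transversal=True)
BOTH = CircuitConfig(include_tangential=True, include_transversal=True)


@pytest.fixture(scope="session")
def stim():
    return Stimulus()


@pytest.fixture(scope="session")
def ntc_trace(stim):
    """Single tangential (NTC) memristor under the canonical drive."""
    return simulate(TANG_ONLY, stim)


@pytest.fixture(scope="session")
def hp_trace(stim):
    """Single transversal (HP) memristor under the canonical drive."""
    return simulate(TRAN_ONLY, stim)


@pytest.fixture(scope="session")
def ntc_c60_trace(stim):
    return simulate(replace(TANG_ONLY, capacitance=60e-6), stim)


@pytest.fixture(scope="session")
def hp_c60_trace(stim):
    return simulate(replace(TRAN_ONLY, capacitance=60e-6), stim)


@pytest.fixture(scope="session")
def both_trace(stim):
    return simulate(BOTH, stim)


@pytest.fixture(scope="session")
def both_c60_trace(stim):
    return simulate(replace(BOTH, capacitance=60e-6), stim)


def make_loop_trace(t, v, i, samples_per_period, n_periods=1):
    """Wrap raw (t, v, i) arrays as a trace with inactive state channels."""
    t = np.asarray(t, dtype=float)
    nan = np.full_like(t, np.nan)
    zero = np.zeros_like(t)
    return SimulationTrace(
        t=t,
        v=np.asarray(v, dtype=float),
        i_tang=zero,
        i_tran=zero,
        i_c=zero,
        i_total=np.asarray(i, dtype=float),
        temperature=nan,
        x=nan,
        g_tang=nan,
        g_tran=nan,
        samples_per_period=samples_per_period,
        n_periods=n_periods,
        metadata={},
    )


def downsample_trace(trace, stride):
    """Stride-decimate a trace; samples_per_period must divide by stride."""
    assert trace.samples_per_period % stride == 0
    return SimulationTrace(
        t=trace.t[::stride],
        v=trace.v[::stride],
        i_tang=trace.i_tang[::stride],
        i_tran=trace.i_tran[::stride],
        i_c=trace.i_c[::stride],
        i_total=trace.i_total[::stride],
        temperature=trace.temperature[::stride],
        x=trace.x[::stride],
        g_tang=trace.g_tang[::stride],
        g_tran=trace.g_tran[::stride],
        samples_per_period=trace.samples_per_period // stride,
        n_periods=trace.n_periods,
        metadata=trace.metadata,
    )
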
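"""Synthetic noisy (t, v, i) recordings with known ground truth.

Real bioimpedance recordings of skin show three recurring loop morphologies
under sinusoidal drive: a single pinch point displaced from the origin
(transversal sweat-duct pathway dominating, in parallel with the tissue
capacitance), two origin-symmetric pinch points (tangential stratum-corneum
pathway dominating), and strongly asymmetric loops (both pathways
contributing).  This module emulates those three classes by simulating the
matching model circuits and adding instrument-like Gaussian noise to the
current channel only — the source voltage is ideal — so the feature and
classification stack can be exercised with known ground truth.

The model parameters are the circuit defaults; no attempt is made to match
skin-scale conductances, which the circuit models deliberately do not
represent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .engine import SimulationTrace, SolverOptions, simulate
from .loop_features import (
    Tolerances,
    classify_pinch,
    detect_pinch_points,
    lobe_areas,
    origin_symmetry_score,
    UndefinedClassificationError,
)
from .models import CircuitConfig
from .stimulus import Stimulus

__all__ = [
    "Recording",
    "RecordingFormatError",
    "SCENARIO_LABELS",
    "generate_recording",
    "classify_recording",
    "read_recording",
    "write_recording",
]

SCENARIO_LABELS = ("transversal_dominated", "tangential_dominated", "mixed")

_DEFAULT_CAPACITANCE = 60e-6  # F; the smallest value with a visible loop effect


class RecordingFormatError(ValueError):
    """A recording file is missing columns or has a non-uniform time base."""


@dataclass
class Recording:
    """A (t, v, i) series with its generation provenance."""

    t: np.ndarray
    v: np.ndarray
    i: np.ndarray
    label: str = "unknown"
    seed: int | None = None
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.i)):
            raise ValueError("t, v, i must have equal lengths")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def _scenario_config(scenario_label: str) -> CircuitConfig:
    if scenario_label == "transversal_dominated":
        return CircuitConfig(
            include_tangential=False,
            include_transversal=True,
            capacitance=_DEFAULT_CAPACITANCE,
        )
    if scenario_label == "tangential_dominated":
        return CircuitConfig(
            include_tangential=True,
            include_transversal=False,
            capacitance=_DEFAULT_CAPACITANCE,
        )
    if scenario_label == "mixed":
        return CircuitConfig(
            include_tangential=True,
            include_transversal=True,
            capacitance=_DEFAULT_CAPACITANCE,
        )
    raise ValueError(
        f"unknown scenario {scenario_label!r}; expected one of {SCENARIO_LABELS}"
    )


_clean_cache: dict[tuple, SimulationTrace] = {}


def _clean_trace(scenario_label: str, stimulus: Stimulus) -> SimulationTrace:
    key = (
        scenario_label,
        stimulus.amplitude,
        stimulus.frequency,
        stimulus.dc_offset,
        stimulus.n_periods,
    )
    if key not in _clean_cache:
        _clean_cache[key] = simulate(
            _scenario_config(scenario_label), stimulus, SolverOptions()
        )
    return _clean_cache[key]


def generate_recording(
    scenario_label: str,
    stimulus: Stimulus | None = None,
    noise_level: float = 0.01,
    seed: int = 0,
) -> Recording:
    """Simulate a scenario circuit and add current noise.

    Zero-mean Gaussian noise with standard deviation ``noise_level`` times
    the peak current magnitude is added to the current channel only, using a
    generator seeded with ``seed``; the output is fully deterministic for a
    fixed argument tuple.
    """
    if not 0.0 <= noise_level <= 0.2:
        raise ValueError("noise_level must lie in [0, 0.2]")
    stimulus = stimulus or Stimulus()
    trace = _clean_trace(scenario_label, stimulus)
    i = trace.i_total.copy()
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_level * float(np.max(np.abs(i))), size=i.shape)
    return Recording(
        t=trace.t.copy(),
        v=trace.v.copy(),
        i=i,
        label=scenario_label,
        seed=seed,
        noise_level=noise_level,
    )


def _infer_samples_per_period(t: np.ndarray, v: np.ndarray) -> int:
    """Dominant-frequency estimate of the per-period sample count."""
    dt = t[1] - t[0]
    spectrum = np.abs(np.fft.rfft(v - np.mean(v)))
    if len(spectrum) < 2:
        raise RecordingFormatError("recording too short to infer a period")
    k = int(np.argmax(spectrum[1:])) + 1
    duration = dt * (len(t) - 1)
    period = duration / k
    spp = int(round(period / dt))
    if spp < 8:
        raise RecordingFormatError("cannot resolve a drive period in the recording")
    return spp


def _recording_to_trace(recording: Recording) -> SimulationTrace | None:
    """Wrap a recording as a trace over its trailing whole periods.

    The current channel is smoothed with a Savitzky-Golay filter sized to a
    small fraction of the period and then decimated, so sample-level noise
    does not masquerade as loop self-intersections.  Returns None when no
    full period is present.
    """
    t, v, i = recording.t, recording.v, recording.i
    spp = _infer_samples_per_period(t, v)
    n_periods = (len(t) - 1) // spp
    if n_periods < 1:
        return None
    window = max(11, (spp // 25) | 1)
    if window < len(i):
        i = savgol_filter(i, window_length=window, polyorder=3)
    stride = max(1, spp // 800)
    while spp % stride:
        stride -= 1
    n_keep = n_periods * spp + 1
    t, v, i = t[-n_keep:], v[-n_keep:], i[-n_keep:]
    t, v, i = t[::stride], v[::stride], i[::stride]
    nan = np.full_like(t, np.nan)
    zero = np.zeros_like(t)
    return SimulationTrace(
        t=t,
        v=v,
        i_tang=zero,
        i_tran=zero,
        i_c=zero,
        i_total=i,
        temperature=nan,
        x=nan,
        g_tang=nan,
        g_tran=nan,
        samples_per_period=spp // stride,
        n_periods=n_periods,
        metadata={"source": "recording", "label": recording.label},
    )


def classify_recording(recording: Recording, tol: Tolerances | None = None) -> str:
    """Assign a dominance class to a recording from its loop morphology.

    Decision rule, built on the simulated fingerprints of the three circuit
    classes.  A first-quadrant lobe clearly wider than the third-quadrant
    lobe marks the mixed class (only the two-memristor combination inflates
    the Q1 lobe; lobe areas are integrals and therefore robust to current
    noise).  Otherwise two or more pinch points on a point-symmetric loop
    mean the tangential pathway with its parallel capacitance; everything
    else — a displaced single pinch, or a twice-pinched but asymmetric loop —
    is transversal-dominated, with a slope-based fallback for a single
    origin pinch.  Degenerate or unresolvable loops return ``"unknown"``.
    """
    tol = tol or Tolerances()
    try:
        trace = _recording_to_trace(recording)
    except RecordingFormatError:
        return "unknown"
    if trace is None:
        return "unknown"
    period = trace.n_periods - 1
    pinches = detect_pinch_points(trace, period, tol)
    if not pinches:
        return "unknown"
    v_scale = float(np.max(np.abs(trace.v)))
    i_scale = float(np.max(np.abs(trace.i_total)))
    areas = lobe_areas(trace, period)
    if areas[3] > 0 and areas[1] / areas[3] > 1.2:
        return "mixed"
    if len(pinches) >= 2:
        score = origin_symmetry_score(trace, period)
        cut = 0.5 * (tol.symmetry_tol + tol.asymmetry_tol)
        if score < cut:
            return "tangential_dominated"
        return "transversal_dominated"
    pinch = pinches[0]
    if pinch.distance_from_origin(v_scale, i_scale) > tol.pinch_cluster_radius:
        return "transversal_dominated"
    try:
        cls = classify_pinch(pinch, tol)
    except UndefinedClassificationError:
        return "unknown"
    return "tangential_dominated" if cls == "tangential" else "transversal_dominated"


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"t_s": recording.t, "v_V": recording.v, "i_A": recording.i}
    ).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "label": recording.label,
        "seed": recording.seed,
        "noise_level": recording.noise_level,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV; the label defaults to unknown without a sidecar."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("t_s", "v_V", "i_A") if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"recording file missing columns: {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise RecordingFormatError("time base must be uniform and increasing")
    label, seed, noise_level = "unknown", None, 0.0
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        label = sidecar.get("label", "unknown")
        seed = sidecar.get("seed")
        noise_level = sidecar.get("noise_level", 0.0)
    return Recording(
        t=t,
        v=df["v_V"].to_numpy(dtype=float),
        i=df["i_A"].to_numpy(dtype=float),
        label=label,
        seed=seed,
        noise_level=noise_level,
    )
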
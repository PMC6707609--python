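"""Named, reproducible simulation scenarios.

Each scenario bundles one figure-style numerical experiment: the single-model
fingerprints, the negative-amplitude and DC-offset variants, the capacitance
and frequency sweeps of the single models with a parallel capacitance, and
the two-memristor combinations with and without capacitance.  Running a
scenario writes one trace CSV and one feature JSON per sub-run; the forward
simulations contain no randomness, so re-running a scenario reproduces its
outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from pathlib import Path

from .engine import SolverOptions, simulate, write_trace
from .loop_features import Tolerances, extract_features, write_features
from .models import CircuitConfig
from .stimulus import Stimulus

__all__ = ["Scenario", "SCENARIOS", "register_scenario", "run_scenario", "list_scenarios"]

_CAP_SWEEP = (60e-6, 120e-6, 240e-6)
_FREQ_SWEEP = (0.025, 0.05, 0.1)
_BASE_STIMULUS = Stimulus(amplitude=4.5, frequency=0.025, dc_offset=0.0, n_periods=2)

_TANG_ONLY = CircuitConfig(include_tangential=True, include_transversal=False)
_TRAN_ONLY = CircuitConfig(include_tangential=False, include_transversal=True)
_BOTH = CircuitConfig(include_tangential=True, include_transversal=True)


@dataclass(frozen=True)
class Scenario:
    """A named experiment: a set of (sub-run name, circuit, stimulus) triples."""

    name: str
    description: str
    runs: tuple[tuple[str, CircuitConfig, Stimulus], ...]
    solver_options: SolverOptions = field(default_factory=SolverOptions)
    tolerances: Tolerances = field(default_factory=Tolerances)


def _with_cap(config: CircuitConfig, capacitance: float) -> CircuitConfig:
    return replace(config, capacitance=capacitance)


def _build_registry() -> dict[str, Scenario]:
    reg: dict[str, Scenario] = {}

    def add(name: str, description: str, runs) -> None:
        reg[name] = Scenario(name=name, description=description, runs=tuple(runs))

    add(
        "fig2_tangential",
        "Single NTC-thermistor (tangential) memristor, 4.5 V / 0.025 Hz",
        [("tangential", _TANG_ONLY, _BASE_STIMULUS)],
    )
    add(
        "fig2_transversal",
        "Single HP (transversal) memristor, 4.5 V / 0.025 Hz",
        [("transversal", _TRAN_ONLY, _BASE_STIMULUS)],
    )
    add(
        "s1_negative_amplitude",
        "Both single models driven with amplitude -4.5 V",
        [
            ("tangential", _TANG_ONLY, replace(_BASE_STIMULUS, amplitude=-4.5)),
            ("transversal", _TRAN_ONLY, replace(_BASE_STIMULUS, amplitude=-4.5)),
        ],
    )
    add(
        "s2_dc_offset",
        "Both single models with a -0.25 V DC offset on the source",
        [
            ("tangential", _TANG_ONLY, replace(_BASE_STIMULUS, dc_offset=-0.25)),
            ("transversal", _TRAN_ONLY, replace(_BASE_STIMULUS, dc_offset=-0.25)),
        ],
    )
    add(
        "fig3a_capacitance_sweep",
        "Each single model with C in {60, 120, 240} uF at 0.025 Hz",
        [
            (f"{branch}_C{int(c * 1e6)}uF", _with_cap(cfg, c), _BASE_STIMULUS)
            for branch, cfg in (("tangential", _TANG_ONLY), ("transversal", _TRAN_ONLY))
            for c in _CAP_SWEEP
        ],
    )
    add(
        "fig3b_frequency_sweep",
        "Each single model with C = 60 uF at f in {0.025, 0.05, 0.1} Hz",
        [
            (
                f"{branch}_f{f_hz:g}Hz",
                _with_cap(cfg, 60e-6),
                replace(_BASE_STIMULUS, frequency=f_hz),
            )
            for branch, cfg in (("tangential", _TANG_ONLY), ("transversal", _TRAN_ONLY))
            for f_hz in _FREQ_SWEEP
        ],
    )
    add(
        "fig4a_both_memristors",
        "Both memristor models in parallel (no capacitance), several frequencies",
        [
            (f"both_f{f_hz:g}Hz", _BOTH, replace(_BASE_STIMULUS, frequency=f_hz))
            for f_hz in _FREQ_SWEEP
        ],
    )
    add(
        "fig4b_both_plus_capacitance",
        "Both memristor models plus C = 60 uF in parallel, several frequencies",
        [
            (
                f"both_C60uF_f{f_hz:g}Hz",
                _with_cap(_BOTH, 60e-6),
                replace(_BASE_STIMULUS, frequency=f_hz),
            )
            for f_hz in _FREQ_SWEEP
        ],
    )
    return reg


SCENARIOS: dict[str, Scenario] = _build_registry()


def register_scenario(scenario: Scenario) -> None:
    """Add a custom scenario; the name must be new."""
    if scenario.name in SCENARIOS:
        raise ValueError(f"scenario {scenario.name!r} already registered")
    SCENARIOS[scenario.name] = scenario


def run_scenario(
    name: str,
    output_dir: str | Path,
    solver_options: SolverOptions | None = None,
    tolerances: Tolerances | None = None,
    make_plots: bool = False,
):
    """Simulate every sub-run of a scenario and write traces + feature JSON.

    Returns ``{sub_run_name: LoopFeatures}`` for the final simulated period.
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    scenario = SCENARIOS[name]
    options = solver_options or scenario.solver_options
    tol = tolerances or scenario.tolerances
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for run_name, config, stim in scenario.runs:
        trace = simulate(config, stim, options)
        stem = f"{name}__{run_name}"
        write_trace(trace, out / f"{stem}.csv")
        features = extract_features(trace, tol=tol)
        write_features(features, out / f"{stem}.features.json")
        if make_plots:
            _plot_loop(trace, out / f"{stem}.png")
        results[run_name] = features
    return results


def _plot_loop(trace, path: Path) -> None:
    """Decorative V-I loop plot; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(trace.v, trace.i_total * 1e3, lw=0.8)
    ax.axhline(0.0, color="0.8", lw=0.5)
    ax.axvline(0.0, color="0.8", lw=0.5)
    ax.set_xlabel("voltage (V)")
    ax.set_ylabel("current (mA)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def list_scenarios(filter_string: str = "") -> list[str]:
    """Human-readable registry listing, optionally substring-filtered."""
    lines = []
    for name in sorted(SCENARIOS):
        if filter_string and filter_string not in name:
            continue
        sc = SCENARIOS[name]
        lines.append(f"{name}: {sc.description} ({len(sc.runs)} run(s))")
    return lines
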
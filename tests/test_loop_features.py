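"""Loop descriptors against analytic curves and the simulated fingerprints.

Analytic oracles: a figure-eight Lissajous curve (v = sin t, i = sin t cos t)
with known pinch point, branch slopes +-1, lobe areas of 1/3 per quadrant and
clockwise traversal; and a phase-shifted ellipse with a known current lag and
no self-intersection.
"""

import math

import numpy as np
import pytest

from pinchloop import (
    PinchPoint,
    Stimulus,
    Tolerances,
    classify_pinch,
    current_peak_lag,
    detect_pinch_points,
    lobe_areas,
    memductance_extrema,
    origin_symmetry_score,
    per_period_drift,
    phase_angle_range,
    quadrant_orientation,
    simulate,
)
from pinchloop.loop_features import (
    UndefinedClassificationError,
    _signed_quadrant_areas,
    segment_self_intersections,
)
from .conftest import TANG_ONLY, TRAN_ONLY, downsample_trace, make_loop_trace


def figure_eight_trace(n=2000):
    """v = sin t, i = sin t cos t: transversal origin pinch, slopes +-1."""
    theta = np.linspace(0.0, 2 * np.pi, n + 1)
    return make_loop_trace(theta, np.sin(theta), np.sin(theta) * np.cos(theta), n)


def ellipse_trace(psi=0.3, n=2000):
    """v = sin t, i = sin(t - psi): no pinch, current lags by psi."""
    theta = np.linspace(0.0, 2 * np.pi, n + 1)
    return make_loop_trace(theta, np.sin(theta), np.sin(theta - psi), n)


# ---------------------------------------------------------------------------
# pinch detection


def test_figure_eight_has_one_transversal_origin_pinch():
    pinches = detect_pinch_points(figure_eight_trace(), 0)
    assert len(pinches) == 1
    p = pinches[0]
    assert math.hypot(p.v, p.i) < 1e-3
    slopes = sorted((p.slope_branch_1, p.slope_branch_2))
    assert slopes[0] == pytest.approx(-1.0, abs=0.02)
    assert slopes[1] == pytest.approx(1.0, abs=0.02)
    assert classify_pinch(p) == "transversal"


def test_ellipse_has_no_pinch():
    assert detect_pinch_points(ellipse_trace(), 0) == []


def test_pure_resistor_loop_is_degenerate():
    theta = np.linspace(0.0, 2 * np.pi, 2001)
    trace = make_loop_trace(theta, np.sin(theta), 2.5e-4 * np.sin(theta), 2000)
    assert detect_pinch_points(trace, 0) == []


def test_single_model_pinches(ntc_trace, hp_trace):
    """NTC touches the origin with equal slopes; HP crosses with unequal ones."""
    for trace, expected in ((ntc_trace, "tangential"), (hp_trace, "transversal")):
        pinches = detect_pinch_points(trace, 1)
        assert len(pinches) == 1
        p = pinches[0]
        v_scale = np.max(np.abs(trace.v))
        i_scale = np.max(np.abs(trace.i_total))
        assert p.distance_from_origin(v_scale, i_scale) < 0.01
        assert classify_pinch(p) == expected


def test_capacitance_splits_tangential_pinch_symmetrically(ntc_c60_trace):
    pinches = detect_pinch_points(ntc_c60_trace, 1)
    assert len(pinches) == 2
    a, b = pinches
    v_scale = np.max(np.abs(ntc_c60_trace.v))
    i_scale = np.max(np.abs(ntc_c60_trace.i_total))
    assert abs(a.v + b.v) / v_scale < 0.01
    assert abs(a.i + b.i) / i_scale < 0.01
    assert a.distance_from_origin(v_scale, i_scale) > 0.01


def test_capacitance_displaces_transversal_pinch_without_splitting(hp_c60_trace):
    pinches = detect_pinch_points(hp_c60_trace, 1)
    assert len(pinches) == 1
    v_scale = np.max(np.abs(hp_c60_trace.v))
    i_scale = np.max(np.abs(hp_c60_trace.i_total))
    assert pinches[0].distance_from_origin(v_scale, i_scale) > 0.01


def brute_force_crossings(trace, period_index):
    """All-pairs segment intersections via shapely, adjacency excluded."""
    from shapely.geometry import LineString

    sl = trace.period_slice(period_index)
    v, i = trace.v[sl], trace.i_total[sl]
    vn = v / np.max(np.abs(v))
    inorm = i / np.max(np.abs(i))
    pts = np.column_stack([vn, inorm])
    n = len(pts) - 1
    found = []
    for a in range(n):
        sa = LineString([pts[a], pts[a + 1]])
        for b in range(a + 2, n):
            d = min(b - a, n - (b - a))
            if d < 2:
                continue
            sb = LineString([pts[b], pts[b + 1]])
            inter = sa.intersection(sb)
            if not inter.is_empty and inter.geom_type == "Point":
                found.append((inter.x, inter.y))
    return found


@pytest.mark.parametrize("fixture", ["ntc_c60_trace", "hp_c60_trace"])
def test_detection_agrees_with_brute_force_oracle(fixture, request):
    """On a coarse loop, every reported pinch matches a brute-force crossing."""
    trace = downsample_trace(request.getfixturevalue(fixture), 20)  # 200 pts
    tol = Tolerances(min_separation_frac=2.0 / 200.0)
    pinches = detect_pinch_points(trace, 1, tol)
    oracle = brute_force_crossings(trace, 1)
    assert len(oracle) >= 1
    v_scale = np.max(np.abs(trace.v[trace.period_slice(1)]))
    i_scale = np.max(np.abs(trace.i_total[trace.period_slice(1)]))
    for ox, oy in oracle:
        assert any(
            math.hypot(p.v / v_scale - ox, p.i / i_scale - oy)
            <= tol.pinch_cluster_radius
            for p in pinches
        )


def test_classify_pinch_edge_cases():
    equal = PinchPoint(v=0.0, i=0.0, slope_branch_1=1.0, slope_branch_2=1.0)
    assert classify_pinch(equal) == "tangential"
    with pytest.raises(UndefinedClassificationError):
        classify_pinch(PinchPoint(v=0.0, i=0.0, slope_branch_1=0.0, slope_branch_2=0.0))


# ---------------------------------------------------------------------------
# orientation, areas, symmetry


def test_figure_eight_lobe_areas_match_closed_form():
    areas = lobe_areas(figure_eight_trace(), 0)
    for q in (1, 2, 3, 4):
        assert areas[q] == pytest.approx(1.0 / 3.0, rel=1e-4)


def test_figure_eight_orientation_and_reversal():
    trace = figure_eight_trace()
    assert quadrant_orientation(trace, 0, 1) == "cw"
    reversed_trace = make_loop_trace(
        trace.t, trace.v[::-1], trace.i_total[::-1], trace.samples_per_period
    )
    assert quadrant_orientation(reversed_trace, 0, 1) == "ccw"


def test_model_orientations(ntc_trace, hp_trace):
    """First-quadrant loops run counter-clockwise for both models; in the
    third quadrant the HP loop is clockwise, the NTC loop counter-clockwise."""
    assert quadrant_orientation(hp_trace, 1, 1) == "ccw"
    assert quadrant_orientation(hp_trace, 1, 3) == "cw"
    assert quadrant_orientation(ntc_trace, 1, 1) == "ccw"
    assert quadrant_orientation(ntc_trace, 1, 3) == "ccw"


def test_quadrant_areas_partition_total_area(both_trace):
    areas, total = _signed_quadrant_areas(both_trace, 1)
    assert sum(areas.values()) == pytest.approx(total, rel=1e-12, abs=1e-18)


def test_ntc_lobes_balanced_both_model_lobes_not(ntc_trace, both_trace):
    sym = lobe_areas(ntc_trace, 1)
    assert sym[1] / sym[3] == pytest.approx(1.0, abs=0.05)
    asym = lobe_areas(both_trace, 1)
    assert asym[1] > asym[3]


def test_frozen_resistor_has_no_area():
    theta = np.linspace(0.0, 2 * np.pi, 2001)
    trace = make_loop_trace(theta, np.sin(theta), 3e-4 * np.sin(theta), 2000)
    areas = lobe_areas(trace, 0)
    scale = 3e-4  # v_scale * i_scale
    assert all(a < 1e-9 * scale for a in areas.values())


def test_symmetry_score_zero_for_point_symmetric_loops(ntc_c60_trace):
    assert origin_symmetry_score(figure_eight_trace(), 0) < 1e-3
    assert origin_symmetry_score(ntc_c60_trace, 1) < 0.02


def test_symmetry_score_flags_combined_model_loop(both_trace):
    assert origin_symmetry_score(both_trace, 1) > 0.05


# ---------------------------------------------------------------------------
# time-domain descriptors


def test_memductance_extrema_positions(ntc_trace, hp_trace):
    period = ntc_trace.period
    maxima = memductance_extrema(ntc_trace, 1, "tangential")
    assert len(maxima) == 2
    rel_times = sorted((t - period) / period for t, _ in maxima)
    assert rel_times[0] == pytest.approx(0.25, abs=0.10)
    assert rel_times[1] == pytest.approx(0.75, abs=0.10)
    hp_maxima = memductance_extrema(hp_trace, 1, "transversal")
    assert len(hp_maxima) == 1
    assert (hp_maxima[0][0] - period) / period == pytest.approx(0.5, abs=0.05)


def test_memductance_extrema_plateau_and_errors(ntc_trace):
    theta = np.linspace(0.0, 40.0, 4001)
    flat = make_loop_trace(theta, np.sin(theta), np.sin(theta), 4000)
    flat.g_tang = np.full_like(theta, 2.5e-4)
    maxima = memductance_extrema(flat, 0, "tangential")
    assert maxima == [(0.0, 2.5e-4)]
    with pytest.raises(ValueError, match="not active"):
        memductance_extrema(ntc_trace, 1, "transversal")


def test_current_peak_lag_signs(ntc_trace, hp_trace):
    lag_max, lag_min = current_peak_lag(ntc_trace, 1)
    assert lag_max > 0 and lag_min > 0
    lag_max, lag_min = current_peak_lag(hp_trace, 1)
    assert lag_max > 0 and lag_min < 0


def test_current_peak_lag_analytic_ellipse():
    psi = 0.3
    trace = ellipse_trace(psi=psi)
    lag_max, lag_min = current_peak_lag(trace, 0)
    assert lag_max == pytest.approx(psi, abs=0.01)
    assert lag_min == pytest.approx(psi, abs=0.01)


def test_in_phase_resistor_has_zero_lag():
    theta = np.linspace(0.0, 2 * np.pi, 2001)
    trace = make_loop_trace(theta, np.sin(theta), np.sin(theta), 2000)
    lag_max, lag_min = current_peak_lag(trace, 0)
    one_sample = 2 * np.pi / 2000
    assert abs(lag_max) <= one_sample and abs(lag_min) <= one_sample


def test_per_period_drift_offset_behaviour():
    offset = Stimulus(dc_offset=-0.25)
    hp = simulate(TRAN_ONLY, offset)
    assert all(abs(d) > 1e-3 for d in per_period_drift(hp)["x"])
    ntc = simulate(TANG_ONLY, offset)
    swing = np.ptp(ntc.temperature[ntc.samples_per_period:])
    assert abs(per_period_drift(ntc)["temperature"][1]) < 1e-3 * swing


def test_per_period_drift_requires_two_periods():
    theta = np.linspace(0.0, 2 * np.pi, 2001)
    trace = make_loop_trace(theta, np.sin(theta), np.sin(theta), 2000)
    with pytest.raises(ValueError, match="2 simulated periods"):
        per_period_drift(trace)


# ---------------------------------------------------------------------------
# phase angles


def test_phase_angle_range_constant_conductance():
    """alpha = arctan(B/G): 2.10 degrees for G = 1/3890 S, C = 60 uF, f = 25 mHz."""
    tiny_drive = simulate(TANG_ONLY, Stimulus(amplitude=1e-9))
    lo, hi = phase_angle_range(tiny_drive, 1, 60e-6, 0.025)
    expected = math.degrees(math.atan(2 * math.pi * 0.025 * 60e-6 * 3890.0))
    assert lo == pytest.approx(expected, abs=1e-4)
    assert hi == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(2.10, abs=0.005)


def test_phase_angle_range_zero_capacitance(ntc_trace):
    assert phase_angle_range(ntc_trace, 1, 0.0, 0.025) == (0.0, 0.0)


def test_phase_angle_monotone_in_conductance(ntc_trace, hp_c60_trace):
    lo1, hi1 = phase_angle_range(ntc_trace, 1, 60e-6, 0.025)
    assert lo1 <= hi1
    # halving G at fixed B strictly increases alpha
    b = 2 * math.pi * 0.025 * 60e-6
    g = 2.5707e-4
    assert math.atan(b / (g / 2)) > math.atan(b / g)


def test_phase_angle_requires_single_memristor(both_trace):
    with pytest.raises(ValueError, match="exactly one"):
        phase_angle_range(both_trace, 1, 60e-6, 0.025)


def test_higher_frequency_same_susceptance_differs_in_state_change():
    """Equal B = 2*pi*f*C with different f gives different conductance extrema:
    the faster drive leaves less time for state change within a period."""
    slow = simulate(TANG_ONLY, Stimulus(frequency=0.025))
    fast = simulate(TANG_ONLY, Stimulus(frequency=0.05))
    sl = slow.period_slice(1)
    fa = fast.period_slice(1)
    assert np.max(fast.g_tang[fa]) < np.max(slow.g_tang[sl])
    # hence equal-susceptance circuits (0.05 Hz/60 uF vs 0.025 Hz/120 uF)
    # produce different phase ranges even though B matches
    a_fast = phase_angle_range(fast, 1, 60e-6, 0.05)
    a_slow = phase_angle_range(slow, 1, 120e-6, 0.025)
    assert a_fast != a_slow
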
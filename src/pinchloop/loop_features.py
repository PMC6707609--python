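"""Quantitative descriptors of pinched hysteresis loops in the V-I plane.

A memristor driven by a periodic zero-mean voltage traces a closed loop in
the voltage-current plane whose two branches meet at one or more *pinch
points*.  This module turns the qualitative morphology of such loops into
numbers: where the pinch points are and how many there are, whether the
branches cross them with different slopes (transversal) or touch with equal
slopes (tangential), the traversal orientation and lobe area per quadrant,
how point-symmetric the loop is about the origin, where the memductance
extrema fall within the period, how far the current peaks lag the voltage
peaks, how much the device state drifts from period to period, and the range
of the capacitive phase angle ``alpha = arctan(2*pi*f*C / G)`` over a period.

Pinch points are found geometrically on the sampled loop polyline, in
coordinates normalized by the period's voltage and current scales: exact
self-intersections are located by segment-pair intersection, and *touching*
pinches — where the two branches meet with equal slopes and therefore need
not produce a transversal crossing of the discretized curves — are caught by
a point-proximity pass.  Candidates are merged by single-linkage clustering
so that a band of near-coincident contacts around a tangential pinch
collapses to one reported point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

import shapely

__all__ = [
    "Tolerances",
    "PinchPoint",
    "LoopFeatures",
    "DegenerateLoopError",
    "UndefinedClassificationError",
    "detect_pinch_points",
    "classify_pinch",
    "quadrant_orientation",
    "lobe_areas",
    "origin_symmetry_score",
    "memductance_extrema",
    "current_peak_lag",
    "per_period_drift",
    "phase_angle_range",
    "extract_features",
    "write_features",
]

_DEGENERATE_THICKNESS = 1e-6  # normalized transverse extent below which a loop is flat


class DegenerateLoopError(ValueError):
    """The V-I trace encloses no area (e.g. a pure resistor)."""


class UndefinedClassificationError(ValueError):
    """Both branch slopes vanish; the pinch cannot be classified."""


@dataclass(frozen=True)
class Tolerances:
    """Geometric tolerances for pinch detection and classification.

    All radii are fractions of the normalized axes (voltage and current each
    scaled to peak magnitude 1 over the analysed period).

    Parameters
    ----------
    pinch_cluster_radius : float
        Intersection candidates closer than this (single linkage) merge into
        one pinch point.
    slope_equality_rel : float
        Relative slope difference below which the two branches count as
        touching with equal slopes (tangential).
    symmetry_tol : float
        Origin-symmetry score below which a loop counts as point-symmetric.
    asymmetry_tol : float
        Score above which a loop counts as clearly asymmetric.
    touch_radius : float
        Segment-to-segment distance below which two remote parts of the
        curve count as touching (catches tangential pinches, where the
        branches meet without a transversal crossing).
    slope_window : int
        Half-width, in samples, of the local least-squares fit used for the
        branch slopes at a pinch.
    min_separation_frac : float
        Candidate pairs closer than this fraction of the period (cyclic index
        distance) are ignored, so the slow turning regions of the loop are
        not mistaken for self-contacts.
    """

    pinch_cluster_radius: float = 0.01
    slope_equality_rel: float = 0.1
    symmetry_tol: float = 0.02
    asymmetry_tol: float = 0.05
    touch_radius: float = 1e-4
    slope_window: int = 5
    min_separation_frac: float = 1.0 / 64.0

    def __post_init__(self) -> None:
        for name in ("pinch_cluster_radius", "slope_equality_rel", "symmetry_tol",
                     "asymmetry_tol", "touch_radius", "min_separation_frac"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class PinchPoint:
    """A meeting point of the two loop branches, with the local branch slopes."""

    v: float
    i: float
    slope_branch_1: float
    slope_branch_2: float

    def distance_from_origin(self, v_scale: float, i_scale: float) -> float:
        """Normalized distance of the pinch from the origin of coordinates."""
        return math.hypot(self.v / v_scale, self.i / i_scale)


@dataclass
class LoopFeatures:
    """Bundle of all loop descriptors for one period of a trace."""

    pinch_points: list[PinchPoint]
    pinch_count: int
    pinch_class: str  # transversal | tangential | none
    orientation_q1: str  # cw | ccw | undefined
    orientation_q3: str
    lobe_area_q1: float
    lobe_area_q2: float
    lobe_area_q3: float
    lobe_area_q4: float
    origin_symmetry_score: float
    phase_min: float | None
    phase_max: float | None
    current_peak_lag: tuple[float, float]
    per_period_drift: dict[str, list[float]] | None
    v_scale: float = 0.0
    i_scale: float = 0.0
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def _loop_arrays(trace, period_index: int):
    sl = trace.period_slice(period_index)
    return trace.t[sl], trace.v[sl], trace.i_total[sl]


def _normalize(v: np.ndarray, i: np.ndarray):
    v_scale = float(np.max(np.abs(v)))
    i_scale = float(np.max(np.abs(i)))
    if v_scale == 0.0 or i_scale == 0.0:
        raise DegenerateLoopError("zero voltage or current span")
    return v / v_scale, i / i_scale, v_scale, i_scale


def _shoelace(xs: np.ndarray, ys: np.ndarray) -> float:
    """Signed area of the closed polygon through (xs, ys)."""
    return 0.5 * float(
        np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
    )


def _cyclic_sep(ii: np.ndarray, jj: np.ndarray, n: int) -> np.ndarray:
    d = np.abs(ii - jj)
    return np.minimum(d, n - d)


def _loop_thickness(vn: np.ndarray, inorm: np.ndarray) -> float:
    """Transverse extent of the normalized loop: second singular value of the
    centered point cloud.  Near zero for a retraced line (pure resistor)."""
    pts = np.column_stack([vn - np.mean(vn), inorm - np.mean(inorm)])
    return float(np.linalg.svd(pts, compute_uv=False)[-1] / math.sqrt(len(vn)))


def segment_self_intersections(
    pts: np.ndarray, min_separation: int, block: int = 256
) -> list[tuple[float, float, int, int, float]]:
    """Exact self-intersections of an open polyline.

    Returns ``(x, y, seg_a, seg_b, 0.0)`` tuples for every non-degenerate
    crossing of segment pairs whose cyclic index separation is at least
    ``min_separation``.  Exhaustive over all pairs, evaluated in blocks.
    """
    a = pts[:-1]
    r = pts[1:] - a
    nseg = len(a)
    out: list[tuple[float, float, int, int, float]] = []
    for lo in range(0, nseg, block):
        hi = min(lo + block, nseg)
        ai = a[lo:hi, None, :]  # (m, 1, 2)
        ri = r[lo:hi, None, :]
        qp = a[None, :, :] - ai  # (m, nseg, 2)
        rxs = ri[..., 0] * r[None, :, 1] - ri[..., 1] * r[None, :, 0]
        ii = np.arange(lo, hi)[:, None]
        jj = np.arange(nseg)[None, :]
        sep_ok = _cyclic_sep(ii, jj, nseg) >= min_separation
        mask = (jj > ii) & sep_ok & (np.abs(rxs) > 1e-15)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (qp[..., 0] * r[None, :, 1] - qp[..., 1] * r[None, :, 0]) / rxs
            u = (qp[..., 0] * ri[..., 1] - qp[..., 1] * ri[..., 0]) / rxs
        mask &= (t >= 0.0) & (t <= 1.0) & (u >= 0.0) & (u <= 1.0)
        for bi, bj in zip(*np.nonzero(mask)):
            gi = lo + bi
            p = a[gi] + t[bi, bj] * r[gi]
            out.append((float(p[0]), float(p[1]), gi, int(bj), 0.0))
    return out


def _segment_pair_distance(a0, a1, b0, b1):
    """Minimum distance between segment pairs, with the closest-point midpoints.

    Vectorized clamped-quadratic solver over stacked pairs of segments
    ``a0->a1`` and ``b0->b1`` (arrays of shape (m, 2)).
    """
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-30, (b * f - c * e) / denom, 0.0)
    s = np.clip(s, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(e > 1e-30, (b * s + f) / e, 0.0)
    t_clamped = np.clip(t, 0.0, 1.0)
    # re-optimize s where t was clamped
    redo = t != t_clamped
    if np.any(redo):
        with np.errstate(divide="ignore", invalid="ignore"):
            s_new = np.where(a > 1e-30, (b * t_clamped - c) / a, 0.0)
        s = np.where(redo, np.clip(s_new, 0.0, 1.0), s)
    t = t_clamped
    pa = a0 + s[:, None] * d1
    pb = b0 + t[:, None] * d2
    dist = np.hypot(pa[:, 0] - pb[:, 0], pa[:, 1] - pb[:, 1])
    mid = 0.5 * (pa + pb)
    return dist, mid


def _touch_candidates(
    pts: np.ndarray, touch_radius: float, min_separation: int
) -> list[tuple[float, float, int, int, float]]:
    """Remote segment pairs whose minimum distance falls below touch_radius.

    Candidate pairs are prefiltered by endpoint proximity (KD-tree) at a
    radius wide enough to cover any segment pair that could come within
    ``touch_radius`` of each other, then screened by the exact
    segment-segment distance.
    """
    n = len(pts) - 1
    seg_len = np.hypot(*(pts[1:] - pts[:-1]).T)
    prefilter = touch_radius + 2.0 * float(np.max(seg_len))
    tree = cKDTree(pts[:-1])
    pairs = tree.query_pairs(prefilter, output_type="ndarray")
    if len(pairs) == 0:
        return []
    sep = _cyclic_sep(pairs[:, 0], pairs[:, 1], n)
    pairs = pairs[sep >= min_separation]
    if len(pairs) == 0:
        return []
    i, j = pairs[:, 0], pairs[:, 1]
    dist, mid = _segment_pair_distance(pts[i], pts[i + 1], pts[j], pts[j + 1])
    keep = dist < touch_radius
    return [
        (float(mid[k, 0]), float(mid[k, 1]), int(i[k]), int(j[k]), float(dist[k]))
        for k in np.nonzero(keep)[0]
    ]


def _cluster_candidates(
    cands: list[tuple[float, float, int, int, float]], radius: float
) -> list[list[tuple[float, float, int, int, float]]]:
    """Single-linkage clustering of candidate points within ``radius``."""
    if not cands:
        return []
    xy = np.array([(c[0], c[1]) for c in cands])
    parent = list(range(len(cands)))

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list] = {}
    for k, c in enumerate(cands):
        groups.setdefault(find(k), []).append(c)
    return list(groups.values())


def _local_slope(v: np.ndarray, i: np.ndarray, idx: int, window: int) -> float:
    lo = max(0, idx - window)
    hi = min(len(v), idx + window + 2)
    vv, ci = v[lo:hi], i[lo:hi]
    var = float(np.var(vv))
    if var < 1e-30:
        return 0.0
    return float(np.cov(vv, ci, bias=True)[0, 1] / var)


def detect_pinch_points(trace, period_index: int, tol: Tolerances | None = None):
    """Locate the pinch points of one period's V-I loop.

    The closed loop polyline is analysed in normalized coordinates; exact
    segment crossings and near-touching sample pairs are clustered within
    ``tol.pinch_cluster_radius`` and each cluster is reported as one
    :class:`PinchPoint` whose branch slopes come from local least-squares
    line fits around the two contacting passes of the curve.  A degenerate
    (area-free) loop yields an empty list.
    """
    tol = tol or Tolerances()
    _, v, i = _loop_arrays(trace, period_index)
    try:
        vn, inorm, v_scale, i_scale = _normalize(v, i)
    except DegenerateLoopError:
        return []
    if _loop_thickness(vn, inorm) < _DEGENERATE_THICKNESS:
        return []
    pts = np.column_stack([vn, inorm])
    nseg = len(pts) - 1
    min_sep = max(2, int(round(nseg * tol.min_separation_frac)))
    cands = segment_self_intersections(pts, min_sep)
    cands += _touch_candidates(pts, tol.touch_radius, min_sep)
    pinches = []
    for cluster in _cluster_candidates(cands, tol.pinch_cluster_radius):
        cx = float(np.mean([c[0] for c in cluster]))
        cy = float(np.mean([c[1] for c in cluster]))
        # prefer an exact crossing, then closest to the cluster centroid
        rep = min(
            cluster,
            key=lambda c: (c[4] > 0.0, (c[0] - cx) ** 2 + (c[1] - cy) ** 2),
        )
        s1 = _local_slope(v, i, rep[2], tol.slope_window)
        s2 = _local_slope(v, i, rep[3], tol.slope_window)
        pinches.append(
            PinchPoint(
                v=cx * v_scale,
                i=cy * i_scale,
                slope_branch_1=s1,
                slope_branch_2=s2,
            )
        )
    pinches.sort(key=lambda p: (p.v, p.i))
    return pinches


def classify_pinch(p: PinchPoint, tol: Tolerances | None = None) -> str:
    """Tangential if the two branch slopes agree within tolerance, else transversal."""
    tol = tol or Tolerances()
    s1, s2 = p.slope_branch_1, p.slope_branch_2
    scale = max(abs(s1), abs(s2))
    if scale < 1e-15:
        raise UndefinedClassificationError(
            "both branch slopes vanish; classification undefined"
        )
    return "tangential" if abs(s1 - s2) / scale < tol.slope_equality_rel else "transversal"


# ---------------------------------------------------------------------------
# areas, orientation, symmetry


def _split_at_axes(v: np.ndarray, i: np.ndarray):
    """Insert exact axis-crossing points into the closed loop polyline."""
    vs = np.append(v, v[0])
    cs = np.append(i, i[0])
    out_v = [vs[0]]
    out_i = [cs[0]]
    for k in range(len(vs) - 1):
        v0, v1 = vs[k], vs[k + 1]
        i0, i1 = cs[k], cs[k + 1]
        crossings = []
        if v0 * v1 < 0:
            s = v0 / (v0 - v1)
            crossings.append((s, 0.0, i0 + s * (i1 - i0)))
        if i0 * i1 < 0:
            s = i0 / (i0 - i1)
            crossings.append((s, v0 + s * (v1 - v0), 0.0))
        for _, cv, ci in sorted(crossings):
            out_v.append(cv)
            out_i.append(ci)
        out_v.append(v1)
        out_i.append(i1)
    return np.array(out_v), np.array(out_i)


def _signed_quadrant_areas(trace, period_index: int) -> tuple[dict[int, float], float]:
    """Signed pie-slice areas per quadrant and the total signed loop area.

    Each polyline segment contributes the signed area of the triangle it
    spans with the origin (half cross product); summed over the closed loop
    this telescopes to the exact shoelace area, so the per-quadrant sums
    partition the total area at the axis crossings exactly.
    """
    _, v, i = _loop_arrays(trace, period_index)
    vv, ii = _split_at_axes(v, i)
    cross = 0.5 * (vv[:-1] * ii[1:] - vv[1:] * ii[:-1])
    mv = 0.5 * (vv[:-1] + vv[1:])
    mi = 0.5 * (ii[:-1] + ii[1:])
    areas = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    quad = np.zeros(len(cross), dtype=int)
    quad[(mv > 0) & (mi > 0)] = 1
    quad[(mv < 0) & (mi > 0)] = 2
    quad[(mv < 0) & (mi < 0)] = 3
    quad[(mv > 0) & (mi < 0)] = 4
    for q in (1, 2, 3, 4):
        areas[q] = float(np.sum(cross[quad == q]))
    return areas, float(np.sum(cross))


def quadrant_orientation(trace, period_index: int, quadrant: int) -> str:
    """Traversal sense of the loop portion in one quadrant.

    Counter-clockwise (positive signed area) -> ``"ccw"``, clockwise ->
    ``"cw"``; below machine scale -> ``"undefined"``.
    """
    if quadrant not in (1, 2, 3, 4):
        raise ValueError("quadrant must be 1..4")
    areas, _ = _signed_quadrant_areas(trace, period_index)
    _, v, i = _loop_arrays(trace, period_index)
    scale = float(np.max(np.abs(v)) * np.max(np.abs(i)))
    a = areas[quadrant]
    if abs(a) <= 1e-12 * max(scale, 1e-300):
        return "undefined"
    return "ccw" if a > 0 else "cw"


def lobe_areas(trace, period_index: int) -> dict[int, float]:
    """Unsigned loop area per quadrant, V*A."""
    areas, _ = _signed_quadrant_areas(trace, period_index)
    return {q: abs(a) for q, a in areas.items()}


def origin_symmetry_score(trace, period_index: int, max_points: int = 1500) -> float:
    """Worst-case normalized distance of the point-reflected loop from itself.

    Zero for a loop perfectly symmetric under ``(v, i) -> (-v, -i)``.
    """
    _, v, i = _loop_arrays(trace, period_index)
    vn, inorm, _, _ = _normalize(v, i)
    coords = np.column_stack([vn, inorm])
    line = shapely.LineString(np.vstack([coords, coords[:1]]))
    stride = max(1, len(coords) // max_points)
    flipped = shapely.points(-coords[::stride])
    return float(np.max(shapely.distance(flipped, line)))


# ---------------------------------------------------------------------------
# time-domain descriptors


def _branch_g(trace, which_branch: str) -> np.ndarray:
    if which_branch in ("tangential", "tang"):
        g = trace.g_tang
    elif which_branch in ("transversal", "tran"):
        g = trace.g_tran
    else:
        raise ValueError("which_branch must be 'tangential' or 'transversal'")
    if not np.isfinite(g).all():
        raise ValueError(f"{which_branch} branch is not active in this trace")
    return g


def memductance_extrema(trace, period_index: int, which_branch: str):
    """Local maxima (time, value) of a branch memductance within one period.

    A constant (plateau) memductance is reported as a single degenerate
    maximum at the period start.
    """
    sl = trace.period_slice(period_index)
    t = trace.t[sl]
    g = _branch_g(trace, which_branch)[sl]
    span = float(np.ptp(g))
    if span <= 1e-12 * float(np.max(np.abs(g))):
        return [(float(t[0]), float(g[0]))]
    idx, _ = find_peaks(g, prominence=1e-4 * span)
    return [(float(t[k]), float(g[k])) for k in idx]


def _wrap_lag(dt: float, period: float) -> float:
    lag = math.fmod(dt, period)
    if lag > period / 2.0:
        lag -= period
    elif lag <= -period / 2.0:
        lag += period
    return lag


def current_peak_lag(trace, period_index: int) -> tuple[float, float]:
    """Lag of the total-current extrema behind the voltage extrema, s.

    Positive means the current peak occurs after the voltage peak; values are
    wrapped to ``(-t_period/2, t_period/2]``.
    """
    t, v, i = _loop_arrays(trace, period_index)
    period = trace.period
    lag_max = _wrap_lag(float(t[np.argmax(i)] - t[np.argmax(v)]), period)
    lag_min = _wrap_lag(float(t[np.argmin(i)] - t[np.argmin(v)]), period)
    return lag_max, lag_min


def per_period_drift(trace) -> dict[str, list[float]]:
    """State change across consecutive period boundaries, per active state."""
    if trace.n_periods < 2:
        raise ValueError("per-period drift needs at least 2 simulated periods")
    bounds = np.arange(trace.n_periods + 1) * trace.samples_per_period
    out: dict[str, list[float]] = {}
    if trace.has_tangential:
        vals = trace.temperature[bounds]
        out["temperature"] = list(np.diff(vals))
    if trace.has_transversal:
        vals = trace.x[bounds]
        out["x"] = list(np.diff(vals))
    return out


def phase_angle_range(
    trace, period_index: int, capacitance: float, frequency: float
) -> tuple[float, float]:
    """Range of the capacitive phase angle over one period, degrees.

    ``alpha = arctan(2*pi*f*C / G)`` evaluated at the period's maximum and
    minimum branch memductance; defined for a single-memristor circuit only.
    """
    if capacitance < 0:
        raise ValueError("capacitance must be >= 0")
    active = [b for b in ("tangential", "transversal")
              if getattr(trace, f"has_{b}")]
    if len(active) != 1:
        raise ValueError(
            "phase angle range is defined for exactly one active memristor branch"
        )
    if capacitance == 0.0:
        return (0.0, 0.0)
    sl = trace.period_slice(period_index)
    g = _branch_g(trace, active[0])[sl]
    b = 2.0 * math.pi * frequency * capacitance
    alpha_min = math.degrees(math.atan(b / float(np.max(g))))
    alpha_max = math.degrees(math.atan(b / float(np.min(g))))
    return alpha_min, alpha_max


# ---------------------------------------------------------------------------
# bundle


def extract_features(
    trace, period_index: int | None = None, tol: Tolerances | None = None
) -> LoopFeatures:
    """Compute the full loop-feature bundle for one period (default: the last).

    The last simulated period is the headline choice because it is closest to
    the periodic steady state; earlier periods remain reachable through
    ``period_index`` and the per-period drift diagnostics.
    """
    tol = tol or Tolerances()
    if period_index is None:
        period_index = trace.n_periods - 1
    _, v, i = _loop_arrays(trace, period_index)
    v_scale = float(np.max(np.abs(v)))
    i_scale = float(np.max(np.abs(i)))

    pinches = detect_pinch_points(trace, period_index, tol)
    if pinches:
        nearest = min(
            pinches, key=lambda p: p.distance_from_origin(v_scale, i_scale)
        )
        try:
            pinch_class = classify_pinch(nearest, tol)
        except UndefinedClassificationError:
            pinch_class = "none"
    else:
        pinch_class = "none"

    areas = lobe_areas(trace, period_index)
    try:
        score = origin_symmetry_score(trace, period_index)
    except DegenerateLoopError:
        score = 0.0

    phase_min = phase_max = None
    meta = trace.metadata or {}
    cfg = meta.get("config", {})
    stim = meta.get("stimulus", {})
    one_memristor = trace.has_tangential != trace.has_transversal
    if one_memristor and "capacitance" in cfg and "frequency" in stim:
        phase_min, phase_max = phase_angle_range(
            trace, period_index, cfg["capacitance"], stim["frequency"]
        )

    drift = per_period_drift(trace) if trace.n_periods >= 2 else None
    return LoopFeatures(
        pinch_points=pinches,
        pinch_count=len(pinches),
        pinch_class=pinch_class,
        orientation_q1=quadrant_orientation(trace, period_index, 1),
        orientation_q3=quadrant_orientation(trace, period_index, 3),
        lobe_area_q1=areas[1],
        lobe_area_q2=areas[2],
        lobe_area_q3=areas[3],
        lobe_area_q4=areas[4],
        origin_symmetry_score=score,
        phase_min=phase_min,
        phase_max=phase_max,
        current_peak_lag=current_peak_lag(trace, period_index),
        per_period_drift=drift,
        v_scale=v_scale,
        i_scale=i_scale,
        metadata={"period_index": period_index, "tolerances": asdict(tol)},
    )


def write_features(features: LoopFeatures, path: str | Path) -> None:
    """Serialize a feature bundle to JSON with units embedded."""
    doc = {
        "pinch_points": [
            {
                "v_V": p.v,
                "i_A": p.i,
                "slope_branch_1_A_per_V": p.slope_branch_1,
                "slope_branch_2_A_per_V": p.slope_branch_2,
            }
            for p in features.pinch_points
        ],
        "pinch_count": features.pinch_count,
        "pinch_class": features.pinch_class,
        "orientation_q1": features.orientation_q1,
        "orientation_q3": features.orientation_q3,
        "lobe_area_VA": {
            "q1": features.lobe_area_q1,
            "q2": features.lobe_area_q2,
            "q3": features.lobe_area_q3,
            "q4": features.lobe_area_q4,
        },
        "origin_symmetry_score": features.origin_symmetry_score,
        "phase_min_deg": features.phase_min,
        "phase_max_deg": features.phase_max,
        "current_peak_lag_s": {
            "max": features.current_peak_lag[0],
            "min": features.current_peak_lag[1],
        },
        "per_period_drift": features.per_period_drift,
        "v_scale_V": features.v_scale,
        "i_scale_A": features.i_scale,
        "metadata": features.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
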
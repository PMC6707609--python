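# Methods

## Scope and model

`pinchloop` simulates the voltage–current behaviour of two canonical
memristor models driven by an ideal sinusoidal voltage source, alone or in
parallel with each other and with a constant capacitance, and reduces the
resulting pinched hysteresis loops to quantitative features.  The setting is
motivated by low-frequency skin bioimpedance: the sweat-duct conductance
pathway behaves like a *transversal* memristor (loop branches cross the
pinch point with different slopes), the surrounding stratum corneum like a
*tangential* one (branches touch with equal slopes), and the tissue adds a
parallel capacitance.  The circuit models are deliberately **not** scaled to
physiological conductances; they are chosen because one is cleanly
tangential and the other cleanly transversal.

### Tangential branch — self-heating NTC thermistor

Conductance and state (device temperature `T`, K):

    G(T)   = [ R0 · exp( β (1/T − 1/T0) ) ]⁻¹
    dT/dt  = (δ/H_C) (T0 − T) + G(T) v² / H_C

with defaults `R0 = 3.89 kΩ`, `T0 = 300 K`, `β = 5·10⁵ K`, `δ = 0.1 W/K`,
`H_C = 0.14 J/K`, and initial `T = 300 K`.  The Joule term is even in `v`,
so the thermal trajectory — and hence the loop — is invariant under a sign
flip of the drive.  The thermal time constant `H_C/δ = 1.4 s` is short
against the 40 s drive period, so the state is close to `T/2`-periodic
already in the second period; at the origin the two loop branches then touch
with equal slopes rather than crossing.

### Transversal branch — linear-drift HP memristor

Memristance and state (normalized doped-layer extension `x ∈ [0, 1]`):

    M(x)   = R_on x + R_off (1 − x)
    dx/dt  = (μ_v R_on / D²) · (v / M(x)) · s

with defaults `R_on = 100 Ω`, `R_off = 16 kΩ`, `D = 10 nm`,
`μ_v = 10⁻¹⁴ m²/(s·V)`, initial `x = 0.76`, and dimensionless slowdown
factor `s = 5·10⁻⁴`, without which the state would saturate almost
immediately at volt-scale, sub-hertz drive.  The drift is odd in `v`, so the
state change accumulates with a DC offset and the loop is sensitive to the
drive's sign.  At the `[0, 1]` boundaries an outward-pushing rate is
replaced by zero (hard clamp, the saturation behaviour of the original
linear-drift model); with the default parameters the boundaries are never
reached on the simulated runs, which a test asserts.

### Circuit

Branch currents add: `i = i_tang + i_tran + i_C` with
`i_tang = G_tang(T) v`, `i_tran = v / M(x)`, `i_C = C dv/dt`.  Because the
source is an ideal voltage, the two state equations decouple — each sees
only `v(t)`.  The small-signal admittance around a state is
`Y = G_tang + G_tran + j·2πfC`, and the capacitive phase angle of a
single-memristor circuit is `α = arctan(2πfC / G)`; its per-period range is
evaluated at the period's conductance extrema.

## Numerics

* **Integration**: SciPy's embedded adaptive Runge–Kutta 4(5) (`RK45`) with
  `rel_tol = 10⁻⁸`, `abs_tol = 10⁻¹⁰` and a maximum step of 1/20 period.
  The states are O(1)–O(300), so these tolerances are conservative; the loop
  geometry downstream needs smooth traces.  A classical fixed-step RK4
  integrator of the same equations, written independently of SciPy, serves
  as a test oracle; at 2·10⁵ steps per period the two agree on the state
  trajectories to better than 10⁻⁷ relative.
* **Sampling**: the dense solution is interpolated onto a uniform grid of
  4000 samples per period (configurable, minimum 1000); all loop features
  are computed from sampled traces, never from raw solver steps.
* **Clamping**: derivative projection inside the right-hand side (no event
  detection); `x` is additionally clipped into `[0, 1]` before the
  memristance is evaluated so solver micro-overshoots cannot leave the
  domain.

## Loop feature extraction

Features are computed per period on the closed V–I polyline in normalized
coordinates (voltage and current each scaled by the period's peak
magnitude).  Headline features use the **final** simulated period, which is
closest to periodic steady state; period-to-period differences are exposed
separately as drift diagnostics.

* **Pinch points** combine two detectors, merged by single-linkage
  clustering within `pinch_cluster_radius` (default 0.01): exact polyline
  self-intersections (vectorized all-pairs segment crossing), and *touch*
  candidates — remote segment pairs whose exact segment-to-segment distance
  falls below `touch_radius` (default 10⁻⁴).  The touch pass is what makes
  tangential pinches detectable: at a tangential pinch the branches meet
  with equal slopes and separate quadratically, so the discretized curves
  need not cross at all; they do, however, run within discretization
  distance of each other over a short arc, which the clustering collapses to
  a single reported point at the contact.  Candidate pairs closer than
  `min_separation_frac` of a period along the curve (default 1/64,
  cyclically) are ignored so the slowly-moving turning regions of the loop
  are not mistaken for self-contacts.
* **Branch slopes** at a pinch come from least-squares line fits over ±5
  samples around each contacting pass, in raw units (A/V).  A pinch is
  *tangential* when the slopes agree within 10% relative, else
  *transversal*.
* **Orientation and lobe areas** use an exact pie-slice partition: every
  segment contributes the signed area of its triangle with the origin, and
  segments are binned by the quadrant of their midpoint after exact
  axis-crossing points have been inserted.  Summed over the closed loop this
  telescopes to the shoelace area, so the per-quadrant sums partition the
  total exactly; their signs give the traversal sense per quadrant.
* **Origin symmetry score** is the maximum over samples of the distance from
  the point-reflected sample `(−v, −i)` to the loop polyline, in normalized
  coordinates (Shapely distance); 0 means perfect point symmetry.
  Defaults: loops below 0.02 are treated as symmetric, above 0.05 as clearly
  asymmetric.
* **Degenerate loops** (a retraced line, e.g. a pure resistor) are detected
  by the second singular value of the centered normalized point cloud and
  yield no pinch points.
* **Memductance extrema** use SciPy peak finding with a small relative
  prominence; a constant branch reports one degenerate maximum at the period
  start.  Current peak lags are argmax/argmin time differences wrapped to
  `(−t_period/2, t_period/2]`.

### Known behaviour worth stating

With the default parameters the *combined* two-memristor loop carries, in
addition to its origin pinch, a genuine second self-intersection near the
negative voltage extreme (around −4.0 V at 0.025 Hz): the thermistor's
conductance keeps rising through the early negative half-period while the
HP branch's falls, folding the third-quadrant lobe tip into a small
counter-rotating sub-loop.  The feature extractor reports it faithfully.
When the capacitance is added, the displaced main crossing plus this
negative-side crossing are the loop's two pinch points.

The capacitor adds an origin-symmetric current component; consequently the
combined-model loop's asymmetry score *drops* when the capacitance is added
(0.054 without C, 0.046 with 60 μF at 0.025 Hz) even though the loop remains
visibly asymmetric.

## Synthetic recordings

The generator emulates the three loop-morphology classes seen in skin
recordings by simulating the matching circuits with the model defaults —
transversal-dominated (HP + 60 μF), tangential-dominated (NTC + 60 μF),
mixed (both + 60 μF) — under the canonical drive (4.5 V, 0.025 Hz, two
periods), then adds zero-mean Gaussian noise to the current channel only
(instrument-like; the source is ideal), with standard deviation expressed as
a fraction of the peak current and a seeded generator for determinism.

What it does **not** emulate: skin-scale conductances and capacitances
(several μS and tens of nF versus the models' hundreds of μS and tens of
μF), electrode polarization, drift between periods of real electrodes, or
the 0.1–2.5 Hz, 1.2 V three-electrode protocol of real measurements.
Passing the recovery tests therefore shows that the feature stack separates
the three loop morphologies at realistic noise, not that it would classify
real skin data unchanged.

The classifier smooths the current with a Savitzky–Golay filter (window 4%
of the inferred period, order 3), decimates to ~800 samples per period, and
applies a fixed decision tree: a Q1/Q3 lobe-area ratio above 1.2 → mixed
(only the two-memristor combination inflates the first-quadrant lobe, and
area integrals are noise-robust); otherwise two or more pinch points on a
point-symmetric loop → tangential-dominated; otherwise → transversal-
dominated, with a slope-based fallback for a single origin pinch.  Measured
recovery with default tolerances: 60/60 correct at 1% noise, 59/60 at 5%.

## Problem sizes

Default runs integrate two drive periods (the scenario convention) at 4000
samples per period; a scenario completes in well under a second and the full
scenario registry in a few seconds.  The fixed-step verification oracle uses
2·10⁵ steps per period.  Recovery statistics use 20 seeds per class and
noise level.

## Open design choices made here

* Sine (not cosine) phase convention, so a positive-amplitude run starts
  with its positive half-period.
* The exponential NTC conductance is read in the standard form
  `G = [R0 exp(β(1/T − 1/T0))]⁻¹`, the only reading under which conductance
  increases with temperature.
* The slowdown factor is treated as dimensionless and applied in every
  simulation that includes the transversal branch.
* `mobility = 0` is allowed and freezes the HP state exactly, giving the
  closed-form Ohmic reference used in tests.
* Feature tolerances (cluster radius 0.01, slope equality 0.1, symmetry
  thresholds 0.02/0.05, touch radius 10⁻⁴) are package defaults chosen to
  separate the qualitative loop classes at the default sampling density; all
  are configurable per call.

## Limitations

* The phase-angle range is defined only for single-memristor circuits, as
  in the underlying admittance decomposition.
* Pinch detection assumes a reasonably dense polyline (hundreds of points
  per period); heavily undersampled loops lose the touch detector (crossings
  are still found).
* No series source impedance or electrode front-end; the source is ideal.
* Non-sinusoidal waveforms are out of scope (the stimulus object is the
  extension point).
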
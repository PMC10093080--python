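# Methods

## The decoding model

A waggle phase is one straight run of the figure-eight dance, described by an
angle from vertical θ (degrees, clockwise positive, in [0, 360)) and a
duration τ timed in whole video frames (τ = Δframes / fps). The package
decodes each phase, or each dance (a bout of phases sharing an id), into a
ground vector:

* **Direction.** On the dark comb "up" stands for the sun's current azimuth,
  so the compass bearing is `(φ_sun(t) + θ) mod 360`. The solar azimuth
  φ_sun is computed from the NOAA solar-calculator equations (Julian
  century → geometric mean longitude/anomaly → equation of center →
  corrected obliquity → declination and equation of time → hour angle).
  Against the published NREL SPA benchmark case the implementation agrees to
  ~0.002°, and against an independently implemented PSA ephemeris it agrees
  to ≤ 0.05° on random samples over 1950–2050 — far below the dance's own
  angular scatter (σ ≈ 13.5°). Azimuth is relative to true north; magnetic
  declination is out of scope. Atmospheric refraction is applied to the
  reported elevation only (it does not affect azimuth); elevation is used
  only for the daylight sanity check (a phase timestamped with the sun at or
  below the horizon indicates a clock/timezone error and is warned about,
  not dropped). The azimuth is evaluated at each phase's timestamp rather
  than once per session because it drifts 2–3° per 10 minutes at midday.
* **Distance.** A linear model `d = v·τ` with one site-estimated calibration
  factor v (m/s). Calibration against a feeder at known range uses
  `v = known_distance / estimator(τ)`; the estimator is the median by
  default (robust to mis-timed phases) and configurable to the mean. The
  literature's nonlinear duration–distance curves are deliberately out of
  scope: a single local factor is what a feeder calibration yields.
* **Projection.** Great-circle destination on a sphere of radius 6,371 km.
  At foraging ranges (≤ 10 km) the difference from an ellipsoidal solution
  is sub-meter, far below the per-waggle accuracy, so the spherical model is
  used throughout (verified against an independent 3D vector-algebra
  formulation to < 0.1 m in tests).

Dance-level decoding uses the vector-sum circular mean of the phase angles
and a duration summary (median by default; the field's tables list the
median η alongside mean μ and SD σ). When the mean resultant length is
numerically zero the mean direction is undefined; the dance carries an
explicit `None` rather than an arbitrary angle and geocoding refuses it.

## Maps and summaries

All planar geometry runs on a local azimuthal-equidistant tangent plane
(x = d·sin(bearing), y = d·cos(bearing) from the plane's origin): bearings
and distances from the origin are exact and the distortion across a ≤ 10 km
window is negligible.

* **Density surface.** Fixed-bandwidth isotropic Gaussian kernel sum over
  endpoints, evaluated on a regular grid covering the endpoints plus a
  two-bandwidth margin, rescaled so the maximum cell is 100, and summarized
  with contour thresholds {0, 20, 40, 60, 80, 98, 100}%. The bandwidth is
  parameterized in ground meters (default σ = 29 m, the one-waggle ground
  accuracy at v = 380 m/s and 13 Hz) so the smoothing scale matches the
  signal's intrinsic resolution; a print-radius parameterization tied to a
  particular map scale would not transfer between sites. Default cell size
  5 m (several cells per ring spacing, grids of a few thousand cells at
  typical sessions). The grid origin defaults to the endpoint centroid,
  making the surface invariant under rigid translation of the endpoint
  swarm.
* **Search area.** The density peak is the argmax cell center (ties resolve
  to the cell nearest the endpoint centroid, then lowest index — determinism
  over aesthetics). The enclosing circle is the minimal enclosing circle
  (via shapely) of the endpoints after discarding the `trim_fraction`
  farthest from the peak; the default is no trimming, so the circle is a
  conservative bound that provably contains every endpoint (asserted to
  1 cm).
* **Sector width.** The smallest arc containing at least a coverage fraction
  of the bearings, found by exhaustive search over arcs anchored at observed
  bearings (the optimum of that family is the global optimum; ties resolve
  to the smallest width, then the earliest anchor). The coverage fraction
  default is 0.9 and is deliberately a free parameter: how a "visual sector"
  is delimited on a published map is not a well-defined statistic.
* **Annotation geometry.** The static grid overlay returns interior line
  coordinates (x = k·cell_px < width, k ≥ 1, and likewise for y); pixel
  scale is px/mm over a reference extent, with the on-screen size of an
  object rounded half-up to whole pixels. Which video dimension corresponds
  to the comb-frame inner width is camera-dependent, so the extent pair is
  always explicit rather than derived from a site default.

## Sampling diagnostics

Three derived quantities characterize a recording configuration:

* per-waggle accuracy `v / f_waggle` — ground meters encoded by one waggle
  movement (~29 m at 380 m/s and 13 Hz): the intrinsic distance resolution;
* ring spacing `v / fps` — the ground quantum induced by frame-quantized
  durations (~6.3 m at 60 fps), visible as concentric endpoint rings;
* Nyquist margin `fps / (2·f_max)` — with waggle oscillations reaching
  ~18 Hz, 60 fps gives a margin of 1.67.

`sampling_sufficient` holds iff ring spacing ≤ per-waggle accuracy, i.e.
frame timing is not the limiting error source. Rounded companions use
half-up rounding (never banker's) so reports are deterministic and match
how such figures are quoted.

## The synthetic session generator

`SimConfig` defaults define the emulated study conditions: a 10-minute
session starting 10:49 UTC on 2022-06-21 (12:49 local CEST) at 46.15° N,
0.64° W; 141 dances, each with 8–14 phases (uniform; the mean of ~11 matches
a real feeder session's ~10.6 phases per dance); a feeder at bearing 90°,
230 m; v_true = 230/0.60 = 383.3 m/s so the noise-free duration is 0.60 s;
duration noise σ = 0.14 s (the pooled scatter reported for feeder-trained
dances), truncated at one frame period; wrapped-normal angular noise
σ = 13.5°, chosen so the ±2σ span is ≈ 54°, the angular sector typical of
feeder recruitment (a modeling choice, not a measured value); per-phase
waggle frequencies N(12.67, 1.89²) Hz, which feed diagnostics but not
geocoding. Wrapped-normal rather than von Mises noise: at these
concentrations the two are indistinguishable and the wrapped normal is
directly composable with the truth angle.

True phase angles are `feeder_bearing − φ_sun(t_phase)`, so simulated comb
angles rotate with the sun exactly as a real dancer's would. Durations are
quantized to frames and re-derived from frames, reproducing the ring
artifact. Dance start times are uniform in the session; phases within a
dance are spaced by the waggle duration plus a fixed 1.5 s return run. All
randomness flows through one `numpy` generator seeded from the config, so
equal configs give bit-identical phase tables. Configs whose duration noise
would truncate more than half the draws are rejected as inconsistent.

What the generator does **not** emulate: within-dance duration correlation
(only a pooled σ is modeled), dance attrition and follower dynamics, odor
effects, multiple or moving resources, decoding errors by the human
observer, and misdirection under visible sky (the hive hardware prevents
it). Passing recovery tests therefore show the *pipeline* is unbiased and
correctly calibrated under the stated noise model — not that real colonies
meet that noise model.

`recovery_report` runs the complete pipeline (optionally self-calibrating
against the known feeder distance) and scores it: per-dance bearing and
distance errors, density-peak-to-feeder ground distance, sector width and
enclosing-circle diameter. Under the default conditions the self-calibrated
v stays within a few percent of truth (the per-dance median duration snaps
to whole frames, so v moves in discrete steps of ~±1 frame around 0.60 s)
and the pooled median absolute bearing error is ≈ 2.8° (σ_angle/√n_phases
times the half-normal median factor).

## Numerical and interface choices

* Angles normalized to [0, 360) on construction; out-of-range angles in CSV
  input are validation errors (reported with line numbers), not silently
  wrapped — a 400° record is a decoding bug upstream.
* Timestamps are timezone-aware UTC everywhere; local wall-clock input must
  carry its offset. Solar geometry makes naive timestamps unsafe.
* CSV round-trips are exact: floats are written with shortest-repr
  precision, timestamps as ISO-8601.
* Pipeline outputs (CSV/JSON/asc) are byte-deterministic for a given config
  and input; JSON keys are sorted.
* The report JSON schema is generated from the pydantic model and shipped as
  package data; the test suite asserts the shipped file matches the model.

## Problem sizes

Default test and example runs use full-size sessions (141 dances, ~1500
phases) and a 20-seed Monte-Carlo sweep for the recovery checks; a whole
sweep completes in seconds on one core, so no down-scaling is needed.

## Known limitations

* Single calibration factor: real duration–distance curves flatten at long
  range; calibrations transfer poorly across sites and seasons.
* Magnetic declination, terrain and elevation are ignored (bearings are true
  north, endpoints are on the sphere).
* The sector-width statistic depends on its coverage fraction; it is a
  descriptive summary, not an estimator of a biological constant.
* The density surface's absolute scale is arbitrary (max = 100); only its
  geometry is meaningful.
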
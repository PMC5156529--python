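# Methods

This note documents the models, conventions and numerical choices in
`ichnos`, in the order data flow through the package.

## Measurement definitions and conventions

All planar coordinates are millimetres; angles are degrees.  Footprint
length is the distance from the posterior tip of the heel to the
anterior tip of the hallux; max width is the width across the distal
metatarsal (ball) region; foot index is 100·width/length.  Step length
is the heel-to-heel distance between successive tracks, stride length
between successive same-side tracks (exactly one opposite-side print
between the pair).  Angle of gait is the unsigned angle between the
trackway midline and the foot's longitudinal axis; a signed variant
(positive = out-toeing) is available behind the `signed_angles` flag of
`gait_metrics`.

Choices the source definitions leave open, fixed here as package
conventions:

* **Foot longitudinal axis** := posterior heel tip → anterior hallux
  tip.  These are the two landmarks the length definition itself names,
  so length and axis are always self-consistent.
* **Trackway midline** := total-least-squares line through the
  midpoints of successive heel pairs, oriented along walking order.
  Heels alternate left and right of the path; fitting through the heels
  directly would tilt the line (the alternating stagger contributes a
  non-zero cross-covariance of order straddle·step/n even for a
  perfectly straight walk), whereas pair midpoints cancel the stagger
  exactly.  With only two usable heels the connecting line is used.
* **Outline-based widths** (when ball/heel landmark pairs are absent):
  maximum caliper width of the outline perpendicular to the foot axis,
  restricted to the anterior 60 % of the length for max width and the
  posterior 30 % for heel width.  The window fractions are our choice;
  they bracket where the ball and heel lie on a hominin print.
* **Missing prints** are explicit gap markers (a footprint record with
  no landmarks, or a `gap_before` flag).  Steps and strides across a
  recorded gap are skipped and logged, never interpolated.  A stride
  whose two end prints are measurable is kept even when the intervening
  opposite-side print is not (that is how a published stride spanning a
  "virtually indiscernible" middle print is measured in the field).
* **Report rounding**: half away from zero, applied only in the
  formatting layer (`ichnos.report`, `_util.round_half_away`); all
  estimates stay unrounded internally.  Published summary tables mix
  truncation and rounding, so tests compare summary means at ±1 in the
  last printed digit.

## Body-size estimators

The three stature methods and three mass methods are affine in
footprint length (or area).  Consequences used throughout:

* averaging per-footprint estimates over a trackway equals estimating
  at the mean footprint dimension — `profile_individual` therefore
  evaluates at the summary means, and the regression-stature value at
  the 261 mm S1 mean equals the mean of the 11 per-print estimates;
* for the **area** regression the relevant mean is the mean of
  per-print length×width products, which the trackway summary carries
  separately (`area_mean`); the product of the two means differs by the
  length–width covariance and does not reproduce the published values.

Footprint length stands in for foot length in the ratio methods, as in
the trackway literature; the bias between the two is documented, not
corrected.  The *Au. afarensis* foot-length:mass ratio is interpreted
as cm/kg, the only unit reading that reproduces the published ranges
(26.1 cm / 0.632 = 41.3 kg).  When an individual's max width is flagged
unreliable (the single S2 print, widened by slippage or a root cast),
the mass regression on area is replaced by the regression on length
(`s2_exception`).

## Recovering the walk-only regressions

The walk-only regression coefficients (stature on footprint length,
mass on footprint area, mass on footprint length, speed on
stride/length) were published elsewhere and are not printed in the
tables this package ships; only their standard errors of estimate
(5.4 cm, 3.7 kg, 3.8 kg) are.  Rather than import uncited numbers, the
defaults are recovered by ordinary least squares from the printed
cells:

| spec | fitted from | n |
|---|---|---|
| stature_by_length | per-print (length, stature) pairs, S1 | 11 |
| mass_by_area | per-print (length×width, mass) pairs, S1 | 11 |
| speed_by_ratio | per-trackway (stride/length, speed) pairs | 4 |
| mass_by_length | slope from pooled (length, mass) pairs, intercept anchored | 12 → 1 |

The recovery is validated cell by cell (`validate_against_paper`):
every printed estimate is recomputed and compared at ±0.3 units for the
regression cells and ±1 cm / ±0.1 kg for the ratio cells, with a short
documented list of cells the printed tables themselves render
inconsistently (sub-millimetre raw lengths rounded before printing, and
two apparent typos).  The recovered line predicts the printed
per-trackway values for G1–G3 and S2 — lengths well outside the 245–274
mm S1 fitting range — to ≤ 0.4 units, which is the practical check that
the affine model, not an overfit, was recovered.

`mass_by_length` is special: only one printed mass (S2's 46.7 kg) is
known to come from the length regression, so a two-parameter fit is
unidentifiable from designated cells.  The package takes the slope from
the pooled 12-pair (length, mass) OLS and re-anchors the intercept
through the S2 point.  This reproduces every printed cell; users who
hold the originally published equation can override any spec from the
YAML configuration.

## Speed

Walking speed uses the dynamic-similarity power law
v = 0.25·g^0.5·L^1.67·h^−1.17 (g defaults to 9.81 m/s²) and the
recovered stride/length regression.  Conventions, each reverse-checked
against the published speed tables:

* the stature entering the power law is the modern-human ratio-method
  interval (h = L_f/0.16 … L_f/0.14), **unrounded** — using the printed
  integer-cm bounds changes two cells by 0.01;
* v decreases with h, so the interval pairs the tallest stature with
  the slowest speed and vice versa; each relative-speed bound divides a
  speed bound by the stature that produced it;
* the regression method's relative speed divides by the
  regression-method stature (0.93 m/s / 1.716 m = 0.54 s⁻¹);
* any estimate above the ~2.2 m/s walk-to-run transition is flagged,
  since only walk-calibrated equations are implemented.

## Elevation rasters

`grid_points` is Delaunay triangulation with barycentric linear
interpolation (scipy), the method used for the site DEMs: exact on
planes, never extrapolating beyond the data z-range, blanking nodes
outside the convex hull.  Default spacing 1 mm.  Contours are
marching-squares level sets (scikit-image `find_contours`) at integer
multiples of the interval (default 2 mm, the interval of the published
contour maps); the saddle ambiguity is resolved by the mean-of-corners
rule that implementation documents.

`measure_from_dem` references depths against a trimmed least-squares
plane (three refit iterations, dropping the worst 20 % of residuals
each time) so a localized depression does not drag the reference
surface down — the published maps do not state their depth reference,
so the local-plane convention is a documented choice.  The depression
mask collects cells deeper than the threshold (default 2 mm, one
contour interval) below the plane; exactly one connected component is
required (speckle under max(9 cells, 5 % of the largest component) is
tolerated), the foot axis is the mask's principal axis oriented so the
deepest end is the heel, and landmarks are the extreme mask cells along
and across the axis.  Accuracy is mask-quantization bound: length is
recovered within ±2·spacing in the seeded round-trip tests.

## Synthetic data

The generator is the package's test substrate; its defaults emulate the
published trackway statistics (step 568 ± 44 mm, angle of gait ~6°,
foot length ≈ 0.158·stature, foot index 40 %), and presets named after
the five track-makers carry the published per-trackway means.

* **Trackway**: heels alternate left/right of the heading line at
  ±straddle/2 (default 60 mm); Euclidean heel-to-heel step lengths are
  drawn N(step_mean, step_sd) truncated below at max(foot length,
  straddle) — the longitudinal advance is derived from the draw, so a
  zero-noise trackway returns exactly the configured step and angle of
  gait, and estimator-recovery experiments have no structural bias.
  Angles are applied as out-toeing, away from the midline.
* **Footprint template**: heel ellipse + midfoot waist + ball lobe +
  adducted hallux nub, parameterized by length/width/heel width; the
  posterior and anterior extremes sit exactly at 0 and L, so template
  length is exactly the landmark length.
* **Raster**: depression depth interpolates linearly heel→toe (default
  8 → 5 mm, deepest at the heel as on the real prints), with an
  optional posterior drag ramp (~100 mm marks are seen on the best
  preserved tracks) tapering linearly to zero; seeded Gaussian
  micro-relief is added on top.  The raster margin automatically covers
  the configured drag length.
* **Survey network**: the standard four-corner test-pit scheme — four
  perimeter targets, six horizontal distances (four sides + both
  diagonals), a closed four-leg levelling loop — with Gaussian noise
  and an optional single-observation blunder.

What the generator does **not** emulate: substrate plasticity and
depth-dependent distortion, overlapping/superimposed prints,
within-trackway trends (fatigue, turning), erosion of print outlines,
and correlated survey errors.  Passing round-trip tests therefore
demonstrate algorithmic correctness on clean geometry, not robustness
to every taphonomic artefact of real tuff surfaces.

## Survey adjustment

Plan: Gauss–Newton least squares on distance residuals
(scipy `least_squares`, Levenberg–Marquardt, convergence 1e-6 mm) from
an incremental two-circle trilateration seed.  The gauge fixes the
first target at the origin and the second on the +x axis, removing the
three planar datum freedoms; with zero redundancy the exact solve is
returned flagged as non-redundant.  Observations are equally weighted
by default (per-observation sigmas are accepted), matching the absence
of a published weighting scheme.

Heights: the levelling closure error (algebraic loop sum) is
distributed equally across the legs — the documented field practice —
after which the loop closes exactly; distance-proportional distribution
is available behind a flag.  An open traverse is propagated with
closure undefined and flagged.  `residual_report` flags residuals above
10 mm by default, the quality figure the original survey reports as
never exceeded; it is a QA threshold, not a reproducible target.  Note
that in a minimally redundant quadrilateral a 25 mm blunder is mostly
absorbed into coordinates (its residual is ~6 mm), so blunder detection
there relies on the blundered observation carrying the *largest*
residual, which the property tests check.

## Problem sizes and determinism

All printed-table computations are exact desk-scale arithmetic on ≤ 13
rows.  The property suites use 50 seeded raster round trips at 2 mm
spacing, 100-seed survey Monte-Carlo runs, 200-trackway estimator
recovery and 1000-trackway distributional calibration — sizes chosen so
the full suite stays fast while the statistical assertions (3 standard
errors) retain power.  Every stochastic component takes an explicit
integer seed through `numpy.random.default_rng`; identical seeds give
bit-identical output.

## Known limitations

* The recovered regression coefficients are reconstructions from
  printed, rounded cells; they match the printed estimates to ≤ 0.3
  units but are not the originally published coefficients.
* Ratio methods inherit the footprint≠foot length bias uncorrected.
* DEM extraction handles a single depression per raster; multi-print
  scenes must be cropped upstream.
* The survey module is site-local Cartesian only — no geodetic
  projections, no 3-D resection, no photogrammetric bundle adjustment.
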
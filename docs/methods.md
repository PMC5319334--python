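# Methods

## Geometry and conventions

All computation happens in a planar, viewer-centred frame: the female's
viewing position in the avenue's central depression is the origin, the +x
axis runs through the centre of the avenue entrance into the display court,
and y is the signed lateral offset (positive right).  Lengths are
centimetres, angles degrees.  Object-to-viewer distance is the planar
Euclidean distance to the object's centroid; whether a field protocol
measures to the centroid or the near edge makes a sub-centimetre difference
at court scale and the centroid is used throughout.

Visual angles come in two conventions, selected by `angle_convention`:

* `exact` (default) — width: the full subtense 2·arctan(w/2d); depth: the
  difference of elevation angles to the near and far edges of a ground-plane
  extent, arctan(h/(d − δ/2)) − arctan(h/(d + δ/2)), for eye height h.
* `small_angle` — the first-order forms w/d and h·δ/d² (radians, converted
  to degrees).  These are within 1% of the exact forms for subtense ratios
  w/d ≤ 0.1, and they make "perfectly even mosaic" analytically exact: a
  court with extent proportional to distance has angle s.d. identically 0.

Depth angles require an eye height; the default of 15 cm approximates a
female standing in the avenue depression and is configurable.  With the eye
in the ground plane (h = 0) depth extents subtend nothing, by construction.
An object whose depth extent would reach the viewer (d ≤ δ/2) is an error
rather than a clamp: it signals a mismeasured table, and clamping would
silently distort the angle distribution.

The field-of-view wedge is the set of points whose bearing from the avenue
axis is at most `fov_half_angle` (default 45°) and whose axial position lies
between the entrance and the far court edge.  Objects outside the wedge are
excluded from every statistic and reported (model attribute / log line),
not raised: they are simply invisible to the choosing female.

The angle-spread statistic uses the sample standard deviation (n − 1) by
default, switchable to the population convention.

## Illusion effect size

The null model for a court is "the same objects on the same occupied
positions, assigned at random": positions and the object set are both
fixed because they are what the bird actually had to work with.  Objects
are atomic — width and depth travel together — so every permuted court is
physically realisable.  For courts of at most 7 visible objects the null is
the full n! enumeration; otherwise 20 000 seeded uniform draws from the
permutation group (with replacement).  The effect size is the standardised
deviate (null mean s.d. − observed s.d.)/null s.d. of s.d.; the p-value is
the add-one estimator (1 + #{null ≤ observed})/(N + 1), ties counted toward
the numerator, in both sampled and exhaustive modes — conservative, and
never exactly zero.  A degenerate null (every permutation gives the same
s.d., e.g. identical objects) reports effect size 0, p = 1 and a flag.
At 10 000 draws the worst-case Monte-Carlo standard error of the p-value is
√(0.25/10 000) = 0.005.

## Reconstruction analyses

Relative placement normalises to the original court footprint derived from
the pre-removal object table: length = maximum axial distance beyond the
entrance, width = twice the maximum lateral offset (the footprint is
symmetric about the line of sight, which maps to y_rel = 0.5; the entrance
maps to x_rel = 0).  Values outside [0, 1] flag objects outside the
original footprint but are not errors.

The step trajectory starts at the fourth distinct object — the smallest
court for which a two-parameter regression leaves meaningful residuals —
and at each addition up to the tenth computes the RMS residual of the
current court state from the *original* gradient line.  Placement events
may repeat an object id (moves); the court state at any time is the latest
event per id, so dump-then-sort and trial-and-error sequences are
representable exactly.

Residual-set comparisons use the statistic RMS(comparison set) − RMS(R1),
an RMS-scale notion of geometric quality; the p-value shuffles individual
residuals between the two groups (group sizes fixed), two-sided with the
add-one estimator, enumerating all C(n, n₁) label assignments when the
pooled size is at most 12.  The signed statistic is reported so one-sided
questions ("are the rebuilt residuals larger?") can be answered by the
caller.  For the angle metric, residuals are deviations from the group mean
angle — the original court's mean for R1 and R3, the first-10's own mean
for R2, paralleling the gradient construction.  The family of 8 tests per
bower (2 dimensions × 2 metrics × 2 pairs) — or any pooled family across
bowers — is corrected by Holm's sequential step-down Bonferroni at
family-wise α = 0.05; signed differences across the family are additionally
tested by the exact two-sided binomial sign test, zeros dropped.

Time-binned trajectories anchor 2-hour half-open bins at 05:30 and cover
daylight (05:30–18:00) only, matching a camera recording window; clearance
is taken to occur at the start of day 0, and event times are minutes since
clearance to avoid timezone arithmetic.  Each bin reports the court state
at the bin's end.  Effect sizes inside trajectory bins default to 1 000
permutation draws per bin (the per-bin quantity is a trend summary, not a
headline test) and are configurable.

## Synthetic courts

The generator emulates exactly the features the statistics consume:

* positions uniform by area over the field-of-view wedge (rejection
  sampling), or Gaussian clusters for sensitivity checks — real courts may
  be spatially clustered in ways no published density describes, so the
  uniform law is the least-informative default;
* extents linear in distance (default slope 0.02 cm/cm, intercept 1 cm)
  plus additive Gaussian noise (default s.d. 0.3 cm) floored at 0.1 cm —
  additive noise matches the linear-regression analysis model; a lognormal
  variant would change tail behaviour but not the rank structure the
  permutation tests use;
* placement timing as an exponential first latency (mean 45 min, the
  observed mean latency of wild males beginning reconstruction) followed by
  exponential gaps (mean 15 min).  These are simulator conveniences, not
  behavioural claims.

The six reconstruction styles all end with every object at its true
position and differ in order and transient error.  The centre-outward
style seeds placement at the on-axis point one quarter of the court length
beyond the entrance — the region directly in the female's line of sight
that real males rebuild first — and ranks objects by distance from it.
Trial-and-error perturbs each initial placement by a 15 cm positional error
and corrects it over two move rounds with halving noise.

What the synthetic courts do **not** emulate: object shape and orientation
(rotating a non-circular object trades visible width against depth),
coloured decorations, avian visual acuity, spatial clustering calibrated to
real courts, or any male-quality covariates.  Tests passing on synthetic
courts therefore validate the statistical machinery — calibration, oracle
agreement, parameter recovery, strategy separability — not ecological
claims about real bowers.

## Numerical choices

* OLS via the closed-form least-squares solve; degenerate designs (fewer
  than 3 objects, zero distance variance) raise typed errors that the CLI
  maps to exit code 3.
* Permutation nulls are fully vectorised (an (N, n) assignment matrix);
  identical seeds give bit-identical results.
* Tie comparisons use an absolute guard of 1e-12 (relative to the observed
  statistic) so float noise cannot flip a tie against conservatism.
* CSV round-trips write 17 significant digits and parse with
  correctly-rounded float conversion, so write-then-read is exact.

## Problem sizes

The simulation studies use the sizes their questions need: 200-object
courts × 500 replicates for slope recovery, 1 000 replicate courts for
type-I calibration (6-object courts, where the 720-permutation null is
exhaustive and the rejection rule exact), 200 replicates × 60 objects for
strategy separation, and 200 replicate 10 000-draw estimates for the
Monte-Carlo precision check.  All run in seconds on one core thanks to the
vectorised nulls.

## Known limitations

* The depth-angle model treats objects as ground-plane extents; tall
  objects (bones standing upright) would need a 3-D model.
* The footprint normalisation is sensitive to a single far-flung original
  object, since it uses the axial maximum; a quantile-based footprint would
  be more robust but no longer maps the far edge to exactly 1.
* The permutation universe does not constrain assignments spatially;
  ecologically implausible rearrangements (a large stone on top of the
  avenue entrance line) count as available to the bird.
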
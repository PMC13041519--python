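# Methods

## Model structure

The package implements a two-phase interaction model between an animal
inside (or at the edge of) a vehicle's swept trajectory and the approaching
vehicle.

**Phase one** is a race between two clocks. The time the animal needs to
clear the trajectory laterally is `T_a = (D_min + l) / (sin θ · S_a) + δ`;
the time it has is `T_v = D_FID / (S_v + cos θ · S_a)`. Only the
perpendicular component of the escape speed clears the width, so `T_a` is
uniquely minimized at θ = 90° and symmetric about it; the along-track
component changes the closing speed, so fleeing away (θ > 90°) buys time.
A collision is possible iff `T_a ≥ T_v`, ties included, compared at full
floating precision. Degenerate inputs (`S_a = 0`) make `T_a` +infinity,
which keeps the predicate total; a non-positive closing speed (animal
out-running the vehicle along-track) is outside the model's domain and
raises an error rather than returning a negative time.

**Phase two** places the animal on the trajectory's width axis at
`D_initial = D_width − D_min` and drifts it for the full interval `T_v` at
the escape speed's cross-trajectory component: `D_collision = D_initial +
sin θ · S_a · T_v`. The collision probability is then the occupied fraction
of the silhouette's *collision window* — a strip exactly
`round(l / scale)` pixel columns wide (minimum 1), full trajectory height,
centered on the column nearest `D_collision` (left-biased by one column for
even widths). Columns outside the raster count in the denominator but
contribute no occupancy, so the probability decays smoothly to zero as the
window slides off either edge; this out-of-bounds crediting is applied
symmetrically at both edges. Treating the full column height as the
denominator encodes the assumption that the animal's altitude within the
trajectory is uniform-random.

### The lateral-drift term

The drift term is the one genuinely open design point in the formula set:
the phase-one clearing motion uses `sin θ` across the width axis, and the
phase-two drift crosses the same axis. The package therefore defaults to
`sin θ` drift (`lateral_term="sin"`), under which the animal always moves
toward its exit edge. An along-track variant (`lateral_term="cos"`), in
which toward-angles drift forward through the plane and away-angles drift
backward, is retained as a configuration switch for sensitivity analysis.
The choice matters: under sin-drift the marginal probability curve over
`D_min` is strongly multimodal, with peaks where arrivals coincide with the
fuselage and the two engines; under cos-drift the mixture of forward and
backward displacements smears these peaks into a single broad mode.

A geometric consequence of sin-drift worth knowing: the sensory-motor delay
δ raises the fraction of interactions where a collision remains *possible*
sharply (it converts escapes into non-escapes), but barely moves the mean
collision probability. The interactions δ flips are exactly the
near-escapers, and a near-escaper's window midpoint has already drifted to
`D_width + l/2 − ε` — the zero-occupancy exit edge — so the flipped
interactions carry almost no probability mass. The collision-possible
fraction is the right diagnostic for δ; the tests use it.

## Behavioral distributions

Escape angle is a two-component uniform mixture: "toward" on
(0.01°, 89.99°) and "away" on (90.01°, 179.99°); exact 0°/90°/180° never
occur. The away weight is 0.42 for a dark vehicle, 0.65 under blue
(483 nm) light, 0.11 under red (631 nm) light.

Flight-initiation distance is Normal(56.2 m, 16.5 m) truncated at zero for
a dark vehicle and for toward-draws under light (attraction to a light
pairs with short FIDs). Truncation is by resampling; zero sits ~3.4 SD
below the mean, so the rejection rate is ~3 × 10⁻⁴ and the induced mean
bias is below 0.1 m. Away-draws under light use Uniform(0, S_v · β), where
β (seconds) is the light's temporal benefit and S_v · β is the maximum
alert distance. An `alert_speed="animal"` switch substitutes the escape
speed for the vehicle speed in that product; it is not the default because
it makes lit scenarios *more* dangerous than the dark baseline (away-draw
FIDs with mean ~20 m, far below the 56.2-m baseline), inverting the
expected ordering of the scenarios.

## Silhouette representation and the parametric stand-in

A silhouette is a binary occupancy grid with a physical width; the scale is
`width_m / columns`, and the occupied-pixel count times `scale²` is the
frontal area. Grayscale images are binarized at a configurable threshold
(default: pixels darker than 50% intensity are surface); text grids are
read as 0/1 matrices. Masks are immutable once constructed and carry a
per-column prefix sum so window queries are O(1) per position.

The bundled generator rasterizes a gear-up, narrow-body-airliner frontal
view from public 737-800 dimensions: a 3.76-m fuselage disk, two 2.0-m
engine nacelles at ±4.85 m, a 0.4-m wing band with 6° dihedral, a 0.3-m
stabilizer band with 7° dihedral, and a fin-root block, on a canvas
spanning the 14.35-m stabilizer span by a 4.3-m crop from nacelle underside
to fuselage crown (the vertical tail above the fin root is excluded as not
strike-relevant at these distances-to-safety). At the default 1031-column
resolution the scale is 0.0139 m/pixel and a 1.15-m goose is 83 pixels.
The generator is deterministic: a given spec and resolution always produce
the bit-identical mask. What it does **not** emulate is the exact raster
the published application digitized from a manufacturer schematic; absolute
probability levels scale roughly with mean silhouette occupancy, so level
quantities (grand means, per-position probabilities) carry that systematic
uncertainty, while ratios, orderings and curve shapes are robust to it.
Tests passing on the synthetic silhouette therefore demonstrate the model's
mechanics and directions of effect, not agreement with any particular
aircraft raster.

## Sweep design and problem sizes

The default grid embeds the published application: S_a ∈ {1, 3, …, 17} m/s,
δ ∈ {0, 0.1, …, 1} s, ten D_min values evenly spaced on [1, 14.35] m
(step 1.4833 m), fifteen S_v values on [70.47, 270.97] m/s (step
14.3214 m/s), ten β values on [0.5, 8.5] s (step 0.8889 s), three light
scenarios. β is enumerated for the no-light scenario too, where it has no
behavioral effect, so the factorial cell count is exactly 445,500 and the
published 500 iterations/cell give 222,750,000 predictions.

Each cell's generator is `default_rng(SeedSequence(master_seed,
spawn_key=(cell_index,)))`: cells are independent, order-insensitive and
individually re-runnable, and a fixed master seed reproduces every output
byte-for-byte. Per cell, the statistic is either the mean phase-two
probability (*expectation* mode, default) or the fraction of Bernoulli
outcomes drawn from those probabilities; the two agree in expectation and
the tests verify agreement within Monte-Carlo error. Reported aggregates
are: per-scenario grand means (mean ± SD over cell means), marginal curves
over each manipulated axis, and behavioral curves binned to 0.1 m of FID or
0.1° of escape angle, accumulated in streaming histograms so full-grid
sweeps run in constant memory.

The package's standing desk-scale choice is the full grid at 100
iterations/cell (44.55 M predictions, ~90 s single-core), used by the
acceptance script and the directional-reproduction tests; Monte-Carlo
standard errors on marginal points are then ~2 × 10⁻⁴, far below every
asserted effect except the δ mean-probability effect discussed above.

## Known limitations

- No risk-assessment delay before escape initiation; `D_FID` is the point
  of commitment. Absolute probabilities are accordingly conservative.
- Linear, constant-speed trajectories for both parties; no altitude
  dynamics and no aerodynamic flow effects near the airframe.
- The no-light away-draw pairing uses the baseline FID distribution; there
  is no mechanism for lights to lengthen toward-draw FIDs.
- The threshold approach angle `arcsin((D_half + l) / D_mid)` classifies
  direct versus indirect approaches but does not enter the sweep, which
  assumes a direct approach throughout.
- Phase one's clearing requirement (`D_min + l`) and phase two's window
  geometry (midpoint at `D_width − D_min`, half-width `l/2`) are anchored
  half a body length apart, so a narrow band of slow escapes is classified
  collision-possible yet scores zero window overlap; this is inherent to
  the formula set and left as-is.
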
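# Methods

## The intersecting-circle fusiform model

The fusiform is modelled as the intersection of two identical circles of
radius `r`. Its two free parameters are the chord `l` between the
vertices (the drawn length) and the width `w` across the middle (twice
each arc's sagitta). Everything else is derived:

```
beta  = 2 atan(w / l)                     apical inner angle
theta = alpha = 2 beta                    central angle = apical tangent angle
l     = cot(beta / 2) w                   inverse of the first relation
r     = (l^2 + w^2) / (4 w)               chord–sagitta relation
a     = theta_rad r
      = (beta_deg / 360) pi (1 + cot^2(beta / 2)) w     one-sided arc
e     = (a - l) / 2                       vertex push-out distance
```

The model's clinical content is that the final wound length equals the
arc `a`, not the drawn length `l`: closing the wound pushes each vertex
outward by `e` along the major axis. Its assumptions are that the drawn
curves really are circular arcs, that the tissue closes without
shortening or stretching along the wound (no elasticity or tissue
redistribution model), and that both arcs are identical. The tangent
angle `alpha` is the quantity most of the surgical literature calls
"the apical/vertex angle"; the inner angle `beta` is half of it, and
keeping the two apart is one of the model's main points.

All angles in the public API are degrees (clinical convention);
conversion to radians happens inside `fusiform.geometry` only. Lengths
are cm throughout; the SVG export maps 1 cm to 10 user units so that a
100%-scale print is true size.

## Inverse solvers and numerical choices

`l/w = cot(beta/2)` inverts in closed form. `a/w` as a function of
`beta` has no closed-form inverse; on the canonical domain
`beta in (0, 90]` (designs at least as long as wide) it is strictly
decreasing from infinity to its minimum `pi/2` at `beta = 90` (the
full-circle limit `l = w`), so `invert_arc_width_ratio` brackets the
unique root and solves with Brent's method (`xtol = 1e-12`), recovering
`beta` to well under 1e-8 degrees in round-trip tests. Ratios below
`pi/2` are rejected as infeasible rather than clamped. Wider-than-long
lenses (`l < w`) are computable forward but flagged non-canonical and
excluded from inverse design: no surgical fusiform is wider than long,
and on `beta > 90` the `a/w` curve is no longer monotone, so the
inverse would be ambiguous there.

Outline sampling pins the two vertices to exactly `(±l/2, 0)` (the
analytically known endpoints) and samples the rest of each arc
uniformly in the central angle; the polyline perimeter converges to
`2a` and is used in tests as an independent discretisation oracle for
the analytic arc length (chord-sum over 10^6 segments agrees to better
than 1e-6 relative).

Displayed values are rounded to 3 decimals; nothing is rounded
internally, and the JSON outputs carry full precision.

## Photographic correction

Raw lengths measured on photographs are in arbitrary photo units.
Preoperative values divide by the preoperative scale `pre_s` (photo
units per cm, the orientation that makes the correction dimensionally
yield cm). The postoperative incision is additionally corrected for the
altitude difference between the two photographs through a reference
object visible in both: `corrected = post_i * pre_r / (post_s *
post_r)`. When `pre_r = post_r` this reduces to scale-only division.
Both rules are linear in the raw value and invariant under joint
rescaling of a photo's units; a missing or non-positive calibrator
raises instead of silently falling back to scale-only correction. The
width and the one-sided designed incision line are preoperative-photo
measurements, so the preoperative rule applies to them.

## Cohort pipeline

`compute_model_columns` evaluates the model per case from the corrected
width and length. `summarize_by_location` reports mean and sample SD
(n−1) per body site (head, neck, abdomen, upper limbs, lower limbs) and
overall; a single-case site is flagged degenerate and its SD reported
as 0. Two paired comparisons are run against the postoperative
incision: the designed length and the designed arc. The t-test is
paired — the two lengths are pre/post measurements of the same incision
— and two-sided at the 0.05 level, with Pearson correlation alongside.
Rows incomplete in either column are dropped listwise with a logged
count. A zero-variance difference vector leaves the p-value explicitly
undefined (never silently 1.0); an exactly constant nonzero shift is
reported as p = 0 with an infinite t statistic.

## Synthetic cohort generator

The generator emulates the validation cohort's structure: 101 cases;
sites drawn categorically with probabilities 66/6/11/13/5 over the five
sites; per-site widths from normals truncated below at 0.05 cm with
site means (SD) of 0.565 (0.175), 0.650 (0.182), 0.726 (0.290),
0.702 (0.232) and 0.702 (0.361) cm for head, neck, abdomen, upper and
lower limbs (the site-mix-weighted overall mean is 0.612 cm); lengths
as width times a length-width ratio from a normal with mean 2.18 and SD
0.39 truncated at 1.05 so every case is canonical. Truncated normals
(not lognormals) are used because only means and SDs are available to
anchor them. The designed incision line is the model arc plus additive
N(0, 0.05 cm) drawing/measurement noise — a default chosen to keep the
designed-arc and model-arc distributions nearly identical, as observed
in practice — floored at 0.01 cm since a drawn line cannot have
negative length. The postoperative incision is the model arc times
(1 + N(0, CV)) with CV = 0.05: multiplicative, because incision lengths
span roughly 0.6–3.6 cm and absolute noise would distort the smallest
lesions. Ages are N(37, 14.5) clipped to [1, 95]; sex is Bernoulli with
female fraction 58/101.

One integer seed drives five independent substreams (sites,
demographics, sizes, design noise, post noise) derived via
`SeedSequence.spawn`, so a seed fixes the cohort byte-for-byte in CSV
form. The photo layer embeds the true cm lengths into raw photo units
with log-normally jittered scales and references, constructed as the
exact algebraic inverse of the correction formulas, so correction
recovers the truth to floating-point accuracy — a round trip, by
design, not a test of measurement realism.

What the generator does not emulate: real lesions are not normally
distributed in size, drawing error is not independent of lesion size,
wound lengthening varies with site-specific skin elasticity and tension
lines, and real photo measurement has perspective error that no scalar
scale removes. Passing pipeline tests on synthetic cohorts therefore
shows the statistical machinery and the model's internal consistency,
not clinical validity; per-site ratio differences can be injected via
config overrides but have no anchored defaults.

## Problem sizes used in tests

The statistical acceptance checks use 200 replicate cohorts of n = 101
for the significance-pattern test (designed-arc vs wound non-significant
in ≥ 90% of replicates, i.e. near-nominal type-I behaviour; designed
length vs wound significant) and a single n = 10^4 draw for parameter
recovery within 3 standard errors — sizes at which the binomial and
Monte-Carlo tolerances are comfortably discriminating.

## Known limitations

- The model is purely geometric: no tissue mechanics, no dog-ear
  prediction, no site-specific healing.
- True-ellipse, rhombus, S-plasty and mosque-shape patterns are out of
  scope; only the circular-arc fusiform is modelled.
- The inverse solvers cover the canonical domain only (`l >= w`).
- Cohort statistics are limited to the two printed paired comparisons;
  no regression or site-level inference is attempted.
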
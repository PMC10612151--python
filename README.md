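# fusiform

Geometry and validation tools for fusiform ("elliptical") skin excision —
the lens-shaped incision formed by two identical intersecting circular
arcs that is the standard pattern for excising small benign skin lesions
with primary closure.

The package is for plastic/dermatologic surgeons and surgical-geometry
researchers who want to (a) derive everything a fusiform design implies —
vertex angles, arc length, final wound length — from the two numbers
actually chosen at the table (length *l* and width *w*), (b) invert those
relations to design an incision from a target angle or wound-length
bound, and (c) run the cohort-style statistical validation of the model
on measured (or simulated) case data.

## The model

Two identical circles of radius *r* intersect; the overlap is the
fusiform. With chord (length) *l* and width *w* (each arc's sagitta is
*w*/2):

- apical inner angle  β = 2·arctan(*w*/*l*)
- central angle = apical tangent angle  θ = α = 2β
  (the tangent angle is what most of the literature calls "the vertex
  angle")
- length from angle  *l* = cot(β/2)·*w*
- circle radius  *r* = (*l*² + *w*²)/(4*w*)  (chord–sagitta relation)
- one-sided arc  *a* = θ_rad·*r* = (β/360°)·π·(1 + cot²(β/2))·*w*
- vertex push-out  *e* = (*a* − *l*)/2

The arc *a* — not the drawn length *l* — predicts the final wound
length: at closure each vertex is pushed outward by *e*, so the scar
spans *l* + 2*e* = *a*. A classic 3:1 design has a vertex (tangent)
angle of 74°, not the often-quoted "under 30°"; a true 30° tangent angle
requires a 7.6:1 design.

## Worked example

```python
from fusiform import FusiformGeometry

g = FusiformGeometry.from_lw(3.0, 1.0)   # the classic 3:1 design, cm
```

Running `python examples/forward_geometry.py` prints:

```
design:              l = 3.0 cm, w = 1.0 cm
apical inner angle:  36.870 deg
apical tangent angle 73.740 deg  (= central angle, the 'vertex angle')
circle radius:       2.500 cm  (= 5.0 x the half-width)
predicted wound:     3.218 cm  (the arc; always >= the designed length)
vertex push-out:     0.109 cm  (each scar end extends this far past the drawn vertex)
```

So a 3 × 1 cm fusiform is cut from circles of radius 2.5 cm, meets its
vertices at 74°, and closes into a wound about 0.22 cm longer than the
drawn length, 0.109 cm beyond each vertex.

The other `examples/` scripts cover inverse design from a target
angle/ratio (`inverse_design.py`), the dimensionless design curves
(`design_curves.py`), printable SVG templates (`svg_template.py`),
photographic measurement correction (`photo_correction.py`) and the
full synthetic-cohort statistical validation
(`synthetic_cohort_analysis.py`), which reproduces the expected
pattern: the paired designed-length vs postoperative-wound comparison
rejects (P < 0.001, r ≈ 0.99) while designed-arc vs wound does not
(P ≈ 0.72) — the wound follows the arc.

## Command line

```bash
fusiform design -l 3 -w 1                      # geometry as JSON
fusiform invert -r 2.5                         # inner angle from a target a/w
fusiform curves --beta-min 10 --beta-max 90 --steps 9   # design-curve CSV
fusiform template -l 3 -w 1 -o lesion.svg      # printable template, 1 cm = 10 mm
fusiform simulate --n 101 --seed 7 -o cohort.csv
fusiform analyze cohort.csv -o summary.json
```

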
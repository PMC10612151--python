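"""Forward geometry of a fusiform design.

Given the two numbers a surgeon chooses — length l and width w of the
excision — compute everything the intersecting-circle model derives:
the vertex angles, the generating-circle radius, the predicted final
wound length (the arc) and the vertex push-out distance.
"""

from fusiform import FusiformGeometry

g = FusiformGeometry.from_lw(3.0, 1.0)  # the classic 3:1 design, cm

print(f"design:              l = {g.spec.length_l} cm, w = {g.spec.width_w} cm")
print(f"apical inner angle:  {g.inner_angle_beta:.3f} deg")
print(f"apical tangent angle {g.tangent_angle_alpha:.3f} deg  (= central angle, the 'vertex angle')")
print(f"circle radius:       {g.radius_r:.3f} cm  (= {g.radius_r / (g.spec.width_w / 2):.1f} x the half-width)")
print(f"predicted wound:     {g.arc_a:.3f} cm  (the arc; always >= the designed length)")
print(f"vertex push-out:     {g.pushout_e:.3f} cm  (each scar end extends this far past the drawn vertex)")
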
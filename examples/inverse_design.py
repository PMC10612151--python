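"""Inverse design: from a target ratio or angle back to the incision.

A surgeon may start from a constraint — "the final wound must be at
most 2.5x the lesion width" or "I want a 30-degree vertex angle" — and
needs the length to draw. Both inversions are shown.
"""

from fusiform import invert_arc_width_ratio, length_from_inner_angle

# 1) bound the final wound: arc a at most 2.5x the width w
beta = invert_arc_width_ratio(2.5)
l_per_w = length_from_inner_angle(beta, 1.0)
print(f"a/w = 2.5  ->  inner angle {beta:.3f} deg, tangent angle {2 * beta:.3f} deg, l/w = {l_per_w:.3f}")
print("  draw the fusiform this many times longer than wide and the scar will be 2.5 widths long")

# 2) the traditional '30-degree apical angle' rule, read as the tangent angle
l_per_w_30 = length_from_inner_angle(30.0 / 2.0, 1.0)
print(f"tangent angle 30 deg  ->  l/w = {l_per_w_30:.3f} (~{l_per_w_30:.1f}:1)")
print("  a 30-degree vertex under the circle model needs a far longer excision than the usual 3:1")
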
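"""Printable incision template.

Writes a true-to-scale SVG (1 cm of tissue = 10 mm on paper at 100%
print scale) of a 3 x 1 cm fusiform with its landmarks marked, for use
as a cut-out drawing guide.
"""

from fusiform import FusiformSpec, write_template

geom = write_template(FusiformSpec(3.0, 1.0), "template_3x1.svg")
print("wrote template_3x1.svg")
print(f"  outline: l = {geom.spec.length_l} cm, w = {geom.spec.width_w} cm")
print(f"  predicted final wound length: {geom.arc_a:.3f} cm")
print("  landmarks A/B are the vertices, D/E the width extremes; print at 100% scale")
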
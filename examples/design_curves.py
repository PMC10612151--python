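"""Dimensionless design curves over the inner angle.

Everything in the model scales with the width, so three ratios — a/w
(final wound per width), l/w (drawn length per width) and e/w (vertex
push-out per width) — summarise every possible canonical design as
functions of the apical inner angle beta in (0, 90] degrees.
"""

import numpy as np

from fusiform import design_curves

table = design_curves(np.arange(10.0, 91.0, 10.0))
print(table.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
print()
print("a/w and l/w fall as the inner angle opens; e/w rises: blunter designs")
print("are shorter but push their vertices out further at closure.")
print("identity check: max |(a/w - l/w) - 2 e/w| =",
      float(np.max(np.abs(table['arc_width_ratio'] - table['length_width_ratio']
                          - 2 * table['pushout_width_ratio']))))
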
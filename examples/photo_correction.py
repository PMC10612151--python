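"""Correcting raw photographic measurements to comparable cm lengths.

Clinical lengths are measured on photographs in arbitrary units and the
pre/post photos sit at different camera altitudes. The preoperative
values divide by the preoperative scale; the postoperative incision is
additionally corrected through a reference object visible in both
photos.
"""

from fusiform import PhotoMeasurement

m = PhotoMeasurement(
    measured_length=266.0,  # photo units, preoperative
    measured_width=122.0,
    pre_i=302.0,            # one-sided designed incision line
    pre_s=200.0,            # preoperative scale: photo units per cm
    pre_r=118.0,            # reference object, preoperative photo units
    post_i=240.0,           # postoperative incision, photo units
    post_s=160.0,           # postoperative scale
    post_r=94.0,            # same reference object, postoperative photo units
)
for name, value in m.correct().items():
    print(f"{name:18s} {value:.3f} cm")
print()
print("the reference-object ratio pre_r/post_r cancels the altitude difference")
print("between the two photographs, so all four lengths are comparable cm values")
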
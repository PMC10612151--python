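"""Scale/reference-object correction of raw photographic measurements.

Lengths measured on clinical photographs are in arbitrary photo units and
depend on camera altitude. Two algebraic corrections convert them to cm:

* preoperative values are divided by the preoperative scale (photo units
  per cm read off a ruler in the photo);
* the postoperative incision is additionally corrected for the altitude
  difference between the two photographs through a reference object
  visible in both:
  ``corrected = raw_post * pre_r / (post_s * post_r)``.

When the two photographs share an altitude (``pre_r == post_r``) the
postoperative rule reduces to scale-only division. The corrections are
linear in the raw value and invariant under joint rescaling of the
postoperative photo units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from .errors import InvalidCalibrationError

__all__ = ["PhotoMeasurement", "correct_preoperative", "correct_postoperative"]


def _check_positive(name: str, value: float) -> None:
    try:
        ok = value > 0
    except TypeError:
        ok = False
    if not ok:
        raise InvalidCalibrationError(f"{name} must be strictly positive, got {value!r}")


def correct_preoperative(raw: float, pre_s: float) -> float:
    """Corrected preoperative length (cm) = raw photo measurement / scale."""
    _check_positive("preoperative scale pre_s", pre_s)
    if raw < 0:
        raise InvalidCalibrationError(f"raw measurement must be non-negative, got {raw!r}")
    return raw / pre_s


def correct_postoperative(raw_post: float, pre_r: float, post_s: float, post_r: float) -> float:
    """Corrected postoperative length (cm), altitude-corrected via reference object.

    ``(raw_post * pre_r) / (post_s * post_r)``. A missing or non-positive
    calibrator fails loudly — there is no silent fallback to scale-only
    correction.
    """
    _check_positive("preoperative reference pre_r", pre_r)
    _check_positive("postoperative scale post_s", post_s)
    _check_positive("postoperative reference post_r", post_r)
    if raw_post < 0:
        raise InvalidCalibrationError(f"raw measurement must be non-negative, got {raw_post!r}")
    return (raw_post * pre_r) / (post_s * post_r)


@dataclass(frozen=True)
class PhotoMeasurement:
    """Raw photo values and calibrators for one excision case.

    All raw lengths are in photo units; scales are photo units per cm.
    ``pre_i`` is the one-sided designed preoperative incision line,
    ``post_i`` the postoperative incision.
    """

    measured_length: float
    measured_width: float
    pre_i: float
    pre_s: float
    pre_r: float
    post_i: float
    post_s: float
    post_r: float

    def __post_init__(self) -> None:
        for name in ("pre_s", "pre_r", "post_s", "post_r"):
            _check_positive(name, getattr(self, name))
        for name in ("measured_length", "measured_width", "pre_i", "post_i"):
            if getattr(self, name) < 0:
                raise InvalidCalibrationError(f"{name} must be non-negative")

    def correct(self) -> Dict[str, float]:
        """All four corrected lengths (cm) for this case.

        The width and the designed incision line are preoperative-photo
        measurements, so the preoperative rule applies to them too.
        """
        return {
            "corrected_length": correct_preoperative(self.measured_length, self.pre_s),
            "corrected_width": correct_preoperative(self.measured_width, self.pre_s),
            "designed_arc": correct_preoperative(self.pre_i, self.pre_s),
            "post_incision": correct_postoperative(
                self.post_i, self.pre_r, self.post_s, self.post_r
            ),
        }
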
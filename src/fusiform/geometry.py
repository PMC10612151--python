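"""Equal-diameter intersecting-circle model of the fusiform excision.

Two identical circles of radius ``r`` intersect; the lens-shaped overlap is
the fusiform. The chord joining the intersection points is the fusiform
length ``l`` (major axis); the segment across the middle is the width ``w``
(minor axis, twice the sagitta of each arc). Three angles describe the
vertex:

* the central angle ``theta`` subtended by one arc at its circle's centre,
* the apical tangent angle ``alpha`` between the two circles' tangents at a
  vertex — the quantity most of the surgical literature calls "the apical
  (vertex) angle",
* the apical inner angle ``beta`` subtended at a vertex by the two width
  endpoints.

The model's key identity is ``theta = alpha = 2*beta``. The arc length of
one side, ``a``, predicts the final (postoperative) wound length, and each
designed vertex is pushed outward by ``e = (a - l) / 2`` when the wound is
closed.

All public angles are in degrees (the unit every clinical value is printed
in); conversion to radians is centralised here. Lengths are in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InfeasibleRatioError, InvalidGeometryError

__all__ = [
    "FusiformSpec",
    "FusiformGeometry",
    "OutlinePolyline",
    "inner_angle_from_lw",
    "angle_relations",
    "length_from_inner_angle",
    "circle_radius",
    "arc_length",
    "pushout_distance",
    "arc_width_ratio_from_beta",
    "invert_arc_width_ratio",
    "design_curves",
    "outline_polyline",
]

#: Smallest arc-to-width ratio the model can attain (the full-circle limit l = w).
MIN_ARC_WIDTH_RATIO = math.pi / 2.0


def _deg2rad(deg: float) -> float:
    return math.radians(deg)


def _rad2deg(rad: float) -> float:
    return math.degrees(rad)


@dataclass(frozen=True)
class FusiformSpec:
    """The two free design parameters of a fusiform excision.

    Parameters
    ----------
    length_l : float
        Chord between the two vertices (major axis), cm. Must be positive.
    width_w : float
        Width across the middle (minor axis), cm. Must be positive; each
        arc's sagitta is ``width_w / 2``.

    Notes
    -----
    The canonical surgical regime is ``length_l >= width_w`` (inner angle
    at most 90°). Wider-than-long lenses are accepted for forward
    computation but flagged as non-canonical via :attr:`is_canonical`.
    """

    length_l: float
    width_w: float

    def __post_init__(self) -> None:
        if not (self.length_l > 0 and math.isfinite(self.length_l)):
            raise InvalidGeometryError(
                f"fusiform length must be a positive finite number, got {self.length_l!r}"
            )
        if not (self.width_w > 0 and math.isfinite(self.width_w)):
            raise InvalidGeometryError(
                f"fusiform width must be a positive finite number, got {self.width_w!r}"
            )

    @property
    def is_canonical(self) -> bool:
        """True when length >= width (inner angle <= 90°), the surgical regime."""
        return self.length_l >= self.width_w

    @property
    def ratio_l_w(self) -> float:
        return self.length_l / self.width_w


def inner_angle_from_lw(spec: FusiformSpec) -> float:
    """Apical inner angle beta (degrees) from the design parameters.

    ``beta = 2 * arctan(w / l)``; beta <= 90° exactly when l >= w.
    """
    return _rad2deg(2.0 * math.atan2(spec.width_w, spec.length_l))


def angle_relations(beta: float) -> tuple[float, float]:
    """Return (tangent angle alpha, central angle theta) for inner angle beta.

    The central angle equals the apical tangent angle and both are twice
    the apical inner angle: ``theta = alpha = 2 * beta``.
    """
    if not (0.0 < beta < 180.0):
        raise InvalidGeometryError(f"inner angle must lie in (0, 180) degrees, got {beta!r}")
    return 2.0 * beta, 2.0 * beta


def length_from_inner_angle(beta: float, width_w: float) -> float:
    """Fusiform length l (cm) realising inner angle ``beta`` at width ``width_w``.

    ``l = cot(beta / 2) * w``; the round trip through
    :func:`inner_angle_from_lw` recovers beta.
    """
    if not (0.0 < beta < 180.0):
        raise InvalidGeometryError(f"inner angle must lie in (0, 180) degrees, got {beta!r}")
    if not (width_w > 0):
        raise InvalidGeometryError(f"width must be positive, got {width_w!r}")
    return width_w / math.tan(_deg2rad(beta) / 2.0)


def circle_radius(spec: FusiformSpec) -> float:
    """Radius r (cm) of the two generating circles.

    Chord–sagitta relation: ``r = (l**2 + w**2) / (4 * w)``, equivalent to
    the circle-centre consistency ``(l/2)**2 + (r - w/2)**2 = r**2``.
    """
    return (spec.length_l**2 + spec.width_w**2) / (4.0 * spec.width_w)


def arc_length(spec: FusiformSpec) -> float:
    """Length a (cm) of one side's circular arc from vertex to vertex.

    ``a = theta_rad * r = (beta_deg/360) * pi * (1 + cot(beta/2)**2) * w``.
    This is the model's prediction of the final wound length; it is never
    shorter than the chord l.
    """
    theta_rad = 2.0 * _deg2rad(inner_angle_from_lw(spec))
    return theta_rad * circle_radius(spec)


def pushout_distance(spec: FusiformSpec) -> float:
    """Vertex push-out distance ``e = (a - l) / 2`` (cm).

    Each designed vertex is displaced outward along the major axis by e
    when the wound is closed, so the final incision spans l + 2e = a.
    """
    return (arc_length(spec) - spec.length_l) / 2.0


def arc_width_ratio_from_beta(beta: float) -> float:
    """Dimensionless a/w as a function of the inner angle beta (degrees)."""
    if not (0.0 < beta <= 180.0):
        raise InvalidGeometryError(f"inner angle must lie in (0, 180] degrees, got {beta!r}")
    half = _deg2rad(beta) / 2.0
    cot_half = 1.0 / math.tan(half)
    return (beta / 360.0) * math.pi * (1.0 + cot_half**2)


def invert_arc_width_ratio(rho: float) -> float:
    """Inner angle beta (degrees) whose arc-to-width ratio a/w equals ``rho``.

    a/w is strictly decreasing in beta on (0°, 90°], from infinity down to
    its minimum pi/2 at beta = 90° (the full-circle limit l = w), so the
    root is unique. Solved by bracketed Brent iteration; no closed form.

    Raises
    ------
    InfeasibleRatioError
        If ``rho`` is below pi/2, which no design can attain.
    """
    if not math.isfinite(rho):
        raise InfeasibleRatioError(f"arc-width ratio must be finite, got {rho!r}")
    if rho < MIN_ARC_WIDTH_RATIO:
        raise InfeasibleRatioError(
            f"arc-width ratio {rho!r} is below the attainable minimum pi/2 "
            f"({MIN_ARC_WIDTH_RATIO:.12f})"
        )
    if rho == MIN_ARC_WIDTH_RATIO:
        return 90.0
    # a/w ~ 1/beta_rad for small beta, so beta_lo ~ 0.5/rho rad brackets from above
    lo = max(_rad2deg(0.25 / rho), 1e-12)
    while arc_width_ratio_from_beta(lo) <= rho:
        lo /= 2.0
    f = lambda b: arc_width_ratio_from_beta(b) - rho
    return float(brentq(f, lo, 90.0, xtol=1e-12, rtol=8.9e-16))


def design_curves(beta_grid: Sequence[float]) -> pd.DataFrame:
    """Dimensionless design-curve table over a grid of inner angles.

    Returns a DataFrame with columns ``beta_deg``, ``arc_width_ratio``
    (a/w), ``length_width_ratio`` (l/w) and ``pushout_width_ratio`` (e/w).
    Over (0°, 90°], a/w and l/w decrease strictly with beta while e/w
    increases, and a/w - l/w = 2 e/w identically.
    """
    beta = np.asarray(beta_grid, dtype=float)
    if beta.size == 0:
        raise InvalidGeometryError("beta grid is empty")
    if np.any(~np.isfinite(beta)) or np.any(beta <= 0.0) or np.any(beta > 90.0):
        raise InvalidGeometryError("beta grid values must lie in (0, 90] degrees")
    half = np.radians(beta) / 2.0
    cot_half = 1.0 / np.tan(half)
    a_w = (beta / 360.0) * np.pi * (1.0 + cot_half**2)
    l_w = cot_half
    e_w = (a_w - l_w) / 2.0
    return pd.DataFrame(
        {
            "beta_deg": beta,
            "arc_width_ratio": a_w,
            "length_width_ratio": l_w,
            "pushout_width_ratio": e_w,
        }
    )


@dataclass(frozen=True)
class FusiformGeometry:
    """All derived quantities of a fusiform design, computed once from its spec.

    Angles in degrees, lengths in cm, ratios dimensionless.
    """

    spec: FusiformSpec
    inner_angle_beta: float
    tangent_angle_alpha: float
    central_angle_theta: float
    radius_r: float
    arc_a: float
    pushout_e: float
    ratio_l_w: float
    ratio_a_w: float
    ratio_e_w: float

    @classmethod
    def from_spec(cls, spec: FusiformSpec) -> "FusiformGeometry":
        beta = inner_angle_from_lw(spec)
        alpha, theta = angle_relations(beta)
        r = circle_radius(spec)
        a = arc_length(spec)
        e = (a - spec.length_l) / 2.0
        w = spec.width_w
        return cls(
            spec=spec,
            inner_angle_beta=beta,
            tangent_angle_alpha=alpha,
            central_angle_theta=theta,
            radius_r=r,
            arc_a=a,
            pushout_e=e,
            ratio_l_w=spec.length_l / w,
            ratio_a_w=a / w,
            ratio_e_w=e / w,
        )

    @classmethod
    def from_lw(cls, length_l: float, width_w: float) -> "FusiformGeometry":
        return cls.from_spec(FusiformSpec(length_l, width_w))

    def as_dict(self) -> Dict[str, float]:
        """Flat mapping of every derived quantity, full precision."""
        return {
            "length_l_cm": self.spec.length_l,
            "width_w_cm": self.spec.width_w,
            "inner_angle_beta_deg": self.inner_angle_beta,
            "tangent_angle_alpha_deg": self.tangent_angle_alpha,
            "central_angle_theta_deg": self.central_angle_theta,
            "radius_r_cm": self.radius_r,
            "arc_a_cm": self.arc_a,
            "pushout_e_cm": self.pushout_e,
            "ratio_l_w": self.ratio_l_w,
            "ratio_a_w": self.ratio_a_w,
            "ratio_e_w": self.ratio_e_w,
            "canonical": self.spec.is_canonical,
        }


@dataclass(frozen=True)
class OutlinePolyline:
    """Sampled closed outline of a fusiform, centroid at the origin.

    ``points`` is an (n, 2) array in cm tracing the upper arc from vertex A
    at (-l/2, 0) to vertex B at (+l/2, 0) and back along the lower arc; the
    first point is not repeated at the end. ``landmarks`` holds the four
    named construction points A, B (vertices) and D, E (width extremes).
    """

    points: np.ndarray
    landmarks: Dict[str, tuple[float, float]] = field(default_factory=dict)

    def perimeter(self) -> float:
        """Total chord-sum length of the closed polyline (cm)."""
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def outline_polyline(spec: FusiformSpec, points_per_arc: int = 129) -> OutlinePolyline:
    """Sample the fusiform outline as a closed polyline.

    The upper arc belongs to the circle centred at ``(0, -(r - w/2))``, the
    lower arc to its mirror image; both pass exactly through the vertices
    ``(±l/2, 0)`` and the width extremes ``(0, ±w/2)``. The polyline
    perimeter converges to ``2 * arc_length(spec)`` as ``points_per_arc``
    grows. Major axis along +x, y up, units cm.
    """
    if points_per_arc < 2:
        raise InvalidGeometryError(f"points_per_arc must be at least 2, got {points_per_arc!r}")
    r = circle_radius(spec)
    theta_rad = 2.0 * _deg2rad(inner_angle_from_lw(spec))
    cy = r - spec.width_w / 2.0  # distance from lens centre to each circle centre
    phi = np.linspace(-theta_rad / 2.0, theta_rad / 2.0, points_per_arc)
    # upper arc, swept left (A) to right (B)
    upper = np.column_stack([r * np.sin(phi), r * np.cos(phi) - cy])
    upper[0] = (-spec.length_l / 2.0, 0.0)  # pin vertices exactly
    upper[-1] = (spec.length_l / 2.0, 0.0)
    lower = upper[::-1].copy()
    lower[:, 1] *= -1.0
    points = np.vstack([upper, lower[1:-1]])
    landmarks = {
        "A": (-spec.length_l / 2.0, 0.0),
        "B": (spec.length_l / 2.0, 0.0),
        "D": (0.0, spec.width_w / 2.0),
        "E": (0.0, -spec.width_w / 2.0),
    }
    return OutlinePolyline(points=points, landmarks=landmarks)
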
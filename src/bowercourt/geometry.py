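"""Viewer-centred court geometry: visual angles, field of view, gradient fits.

Coordinate frame
----------------
The female viewer sits at the origin of a planar frame whose ``+x`` axis runs
from her position in the avenue's central depression through the centre of the
avenue entrance and on into the display court.  ``y`` is the signed lateral
offset (positive to the viewer's right).  All lengths are centimetres, all
angles degrees.

An object of visible width :math:`w` at planar distance :math:`d` subtends the
exact horizontal angle

.. math:: \\theta_w = 2 \\arctan\\!\\left(\\frac{w}{2d}\\right),

while its visible depth :math:`\\delta` (extent along the line of sight, lying
in the ground plane) subtends, for an eye at height :math:`h`,

.. math:: \\theta_d = \\arctan\\!\\frac{h}{d - \\delta/2}
                    - \\arctan\\!\\frac{h}{d + \\delta/2}.

A positive size-distance gradient (extent increasing with distance) equalises
these angles across the court, producing the even angular mosaic behind the
forced-perspective illusion; the standard deviation of the angles measures how
even the mosaic is (smaller = more regular).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "CourtGeometry",
    "CourtObject",
    "GradientFit",
    "VisualAngleSummary",
    "GeometryError",
    "InsufficientDataError",
    "distance_from_viewer",
    "width_visual_angle",
    "depth_visual_angle",
    "in_field_of_view",
    "visible_objects",
    "fit_gradient",
    "angle_summary",
    "object_angles",
]

Dimension = Literal["width", "depth"]
AngleConvention = Literal["exact", "small_angle"]
SdConvention = Literal["sample", "population"]


class GeometryError(ValueError):
    """Invalid geometric input (non-finite coordinates, degenerate sightlines)."""


class InsufficientDataError(ValueError):
    """Too few objects for the requested statistic."""


@dataclass(frozen=True)
class CourtGeometry:
    """Frame and extent of one display court as seen from the avenue.

    Parameters
    ----------
    viewer_xy : tuple of float
        Female's viewing position (cm); conventionally the origin.
    entrance_xy : tuple of float
        Centre of the avenue entrance; must lie on the ``+x`` ray from the
        viewer (the avenue axis).
    court_length : float
        Extent of the court along the axis beyond the entrance, cm.
    court_width : float
        Full lateral extent of the court, cm.
    fov_half_angle : float
        Half-angle of the female's field-of-view wedge, degrees in (0, 90].
    eye_height : float
        Viewer eye height above the court plane, cm.  Depth angles vanish
        when the eye is in the ground plane.
    """

    viewer_xy: tuple[float, float] = (0.0, 0.0)
    entrance_xy: tuple[float, float] = (20.0, 0.0)
    court_length: float = 80.0
    court_width: float = 100.0
    fov_half_angle: float = 45.0
    eye_height: float = 15.0

    def __post_init__(self) -> None:
        vx, vy = self.viewer_xy
        ex, ey = self.entrance_xy
        if not all(math.isfinite(v) for v in (vx, vy, ex, ey)):
            raise GeometryError("non-finite geometry coordinates")
        if self.court_length <= 0 or self.court_width <= 0:
            raise GeometryError("court_length and court_width must be positive")
        if not 0 < self.fov_half_angle <= 90:
            raise GeometryError("fov_half_angle must lie in (0, 90] degrees")
        if self.eye_height < 0:
            raise GeometryError("eye_height must be non-negative")
        if self.avenue_offset <= 0:
            raise GeometryError("entrance must lie strictly ahead of the viewer")
        # entrance on the +x ray from the viewer defines the axis convention
        if abs(ey - vy) > 1e-9 * max(1.0, self.avenue_offset):
            raise GeometryError(
                "entrance must lie on the avenue axis (+x) from the viewer"
            )

    @property
    def avenue_offset(self) -> float:
        """Distance (cm) from the viewer to the avenue entrance."""
        return math.hypot(
            self.entrance_xy[0] - self.viewer_xy[0],
            self.entrance_xy[1] - self.viewer_xy[1],
        )

    @property
    def axis_unit(self) -> tuple[float, float]:
        return (1.0, 0.0)


@dataclass(frozen=True)
class CourtObject:
    """One court decoration (stone, shell, bone) in viewer coordinates.

    ``x`` is measured along the avenue axis from the viewer; ``y`` is the
    signed lateral offset.  ``placed_at`` is minutes since court clearance for
    placement-sequence data; ``placement_rank`` orders the sequence.
    """

    id: str
    x: float
    y: float
    visible_width: float
    visible_depth: float
    placed_at: float | None = None
    placement_rank: int | None = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "visible_width", "visible_depth"):
            if not math.isfinite(getattr(self, name)):
                raise GeometryError(f"object {self.id!r}: non-finite {name}")
        if self.visible_width <= 0 or self.visible_depth <= 0:
            raise GeometryError(f"object {self.id!r}: visible extents must be > 0")
        if self.placed_at is not None and self.placed_at < 0:
            raise GeometryError(f"object {self.id!r}: placed_at must be >= 0")
        if self.placement_rank is not None and self.placement_rank < 1:
            raise GeometryError(f"object {self.id!r}: placement_rank must be >= 1")

    def extent(self, dimension: Dimension) -> float:
        return self.visible_width if dimension == "width" else self.visible_depth


@dataclass(frozen=True)
class GradientFit:
    """OLS fit of visible extent against viewer distance for one court."""

    dimension: Dimension
    slope: float
    intercept: float
    residuals: np.ndarray
    rms: float
    r_squared: float
    n: int

    def predict(self, distances: np.ndarray | float) -> np.ndarray | float:
        """Extent (cm) the fitted gradient predicts at the given distances."""
        return self.intercept + self.slope * np.asarray(distances, dtype=float)


@dataclass(frozen=True)
class VisualAngleSummary:
    """Per-object visual angles for one dimension plus their mean and spread."""

    dimension: Dimension
    angles: np.ndarray
    mean_angle: float
    sd_angle: float


def distance_from_viewer(obj: CourtObject, geom: CourtGeometry) -> float:
    """Planar Euclidean distance (cm) from the viewer to the object centroid."""
    if obj.x <= 0:
        raise GeometryError(
            f"object {obj.id!r}: x must be > 0 (object must lie ahead of the viewer)"
        )
    return math.hypot(obj.x - 0.0, obj.y - 0.0)


def width_visual_angle(
    visible_width: float, dist: float, convention: AngleConvention = "exact"
) -> float:
    """Horizontal angle (degrees) subtended by a frontal extent at distance ``dist``.

    The exact subtense is ``2*arctan(w / 2d)``; the small-angle convention
    returns ``w/d`` radians converted to degrees, accurate to first order.
    """
    if visible_width < 0:
        raise GeometryError("visible_width must be non-negative")
    if dist <= 0:
        raise GeometryError("distance must be positive")
    if convention == "small_angle" and dist <= visible_width / 2:
        # the linearised form breaks down once the object spans the viewer
        raise GeometryError("distance must exceed half the visible width")
    if convention == "small_angle":
        return math.degrees(visible_width / dist)
    return math.degrees(2.0 * math.atan2(visible_width, 2.0 * dist))


def depth_visual_angle(
    visible_depth: float,
    dist: float,
    eye_height: float,
    convention: AngleConvention = "exact",
) -> float:
    """Vertical angle (degrees) between the sightlines to the near and far
    edges of a ground-plane extent of the given depth at distance ``dist``.

    Zero when the eye is in the ground plane.  The small-angle convention uses
    the first-order form ``h * depth / d**2`` radians.
    """
    if visible_depth < 0:
        raise GeometryError("visible_depth must be non-negative")
    if eye_height < 0:
        raise GeometryError("eye_height must be non-negative")
    near = dist - visible_depth / 2.0
    if near <= 0:
        raise GeometryError("object overlaps the viewer: distance <= depth/2")
    if convention == "small_angle":
        return math.degrees(eye_height * visible_depth / dist**2)
    far = dist + visible_depth / 2.0
    return math.degrees(math.atan2(eye_height, near) - math.atan2(eye_height, far))


def in_field_of_view(obj: CourtObject, geom: CourtGeometry) -> bool:
    """True iff the object lies inside the female's field-of-view wedge.

    Membership requires both the bearing from the avenue axis to be at most
    the field-of-view half-angle and the axial position to fall between the
    entrance and the far court edge.
    """
    if obj.x <= 0:
        return False
    bearing = math.degrees(math.atan2(abs(obj.y), obj.x))
    if bearing > geom.fov_half_angle + 1e-12:
        return False
    axial = obj.x - geom.avenue_offset
    return -1e-9 <= axial <= geom.court_length + 1e-9


def visible_objects(
    objects: Iterable[CourtObject], geom: CourtGeometry
) -> list[CourtObject]:
    """Objects inside the field-of-view wedge, input order preserved."""
    return [o for o in objects if in_field_of_view(o, geom)]


def _distances(objects: Sequence[CourtObject], geom: CourtGeometry) -> np.ndarray:
    return np.array([distance_from_viewer(o, geom) for o in objects], dtype=float)


def object_angles(
    objects: Sequence[CourtObject],
    geom: CourtGeometry,
    dimension: Dimension,
    convention: AngleConvention = "exact",
) -> np.ndarray:
    """Visual angle (degrees) of each object in input order."""
    d = _distances(objects, geom)
    if dimension == "width":
        return np.array(
            [
                width_visual_angle(o.visible_width, di, convention)
                for o, di in zip(objects, d)
            ]
        )
    return np.array(
        [
            depth_visual_angle(o.visible_depth, di, geom.eye_height, convention)
            for o, di in zip(objects, d)
        ]
    )


def fit_gradient(
    objects: Sequence[CourtObject],
    geom: CourtGeometry,
    dimension: Dimension,
    *,
    restrict_fov: bool = True,
) -> GradientFit:
    """Regress visible extent on viewer distance (OLS with intercept).

    This is the court's size-distance gradient: a positive slope means larger
    objects sit further from the viewer.  Residuals are returned in input
    order of the retained objects.
    """
    objs = visible_objects(objects, geom) if restrict_fov else list(objects)
    n = len(objs)
    if n < 3:
        raise InsufficientDataError(
            f"gradient fit needs >= 3 objects in the field of view, got {n}"
        )
    d = _distances(objs, geom)
    y = np.array([o.extent(dimension) for o in objs], dtype=float)
    if np.ptp(d) < 1e-12:
        raise GeometryError("degenerate design: zero variance in distance")
    X = np.column_stack([np.ones(n), d])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(beta[0]), float(beta[1])
    resid = y - (intercept + slope * d)
    rms = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-300 else float(1.0 - np.sum(resid**2) / ss_tot)
    return GradientFit(
        dimension=dimension,
        slope=slope,
        intercept=intercept,
        residuals=resid,
        rms=rms,
        r_squared=max(0.0, min(1.0, r2)),
        n=n,
    )


def _sd(values: np.ndarray, convention: SdConvention) -> float:
    ddof = 1 if convention == "sample" else 0
    if values.size <= ddof:
        return 0.0
    return float(np.std(values, ddof=ddof))


def angle_summary(
    objects: Sequence[CourtObject],
    geom: CourtGeometry,
    dimension: Dimension,
    *,
    angle_convention: AngleConvention = "exact",
    sd_convention: SdConvention = "sample",
    restrict_fov: bool = True,
) -> VisualAngleSummary:
    """Per-object visual angles with their mean and standard deviation.

    The s.d. of visual angles is the court's pattern-regularity statistic: a
    perfectly even angular mosaic has s.d. zero, and smaller values indicate a
    stronger forced-perspective illusion.
    """
    objs = visible_objects(objects, geom) if restrict_fov else list(objects)
    if len(objs) < 2:
        raise InsufficientDataError(
            f"angle summary needs >= 2 objects in the field of view, got {len(objs)}"
        )
    angles = object_angles(objs, geom, dimension, angle_convention)
    return VisualAngleSummary(
        dimension=dimension,
        angles=angles,
        mean_angle=float(np.mean(angles)),
        sd_angle=_sd(angles, sd_convention),
    )
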
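"""Depth-of-invasion adenomyosis grading (Bird criteria).

Severity is graded by how deep ectopic endometrial foci reach into the
myometrium: involvement of the inner third is grade I (superficial),
up to two-thirds grade II, and beyond that grade III (deep). The wall
is parameterised by a normalised depth coordinate

    d(p) = dist(p, inner boundary) / (dist(p, inner) + dist(p, outer))

which is 0 on the endometrial-myometrial interface and 1 on the serosal
edge, so the tertile cut-offs become d <= 1/3 and d <= 2/3 regardless of
local wall thickness. A uterus is graded by its deepest focus pixel
(max rule); no foci means grade 0. In very young animals with a thin
wall only the presence/absence of invasion is meaningful, which
``invasion_present`` carries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

from ._rounding import percent_half_up
from .fluoro import rasterize_polygons

GRADES = ("0", "I", "II", "III")


class InvalidGeometryError(ValueError):
    """Inner/outer boundaries that cross or nest incorrectly."""


@dataclass
class UterusSectionGeometry:
    """Wall geometry of one uterine cross-section, in pixel coordinates:
    the endometrial-myometrial interface (inner), the serosal edge
    (outer), and the ectopic focus outlines found in the wall."""

    inner_boundary: list[tuple[float, float]]
    outer_boundary: list[tuple[float, float]]
    foci: list[list[tuple[float, float]]] = field(default_factory=list)
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        inner = Polygon(self.inner_boundary)
        outer = Polygon(self.outer_boundary)
        if not inner.is_valid or not outer.is_valid:
            raise InvalidGeometryError("boundary polygon is invalid")
        if inner.exterior.crosses(outer.exterior) or inner.exterior.intersects(
            outer.exterior
        ):
            raise InvalidGeometryError("inner and outer boundaries intersect")
        if not inner.within(outer):
            raise InvalidGeometryError("inner boundary must lie inside the outer")
        for focus in self.foci:
            if len(focus) < 3:
                raise InvalidGeometryError("focus polygons need >= 3 vertices")


@dataclass
class GradeResult:
    mouse_id: str
    max_normalized_depth: float  # NaN when no focus invades the wall
    grade: str
    invasion_present: bool


def _raster_shape(geometry: UterusSectionGeometry) -> tuple[int, int]:
    _, _, maxx, maxy = Polygon(geometry.outer_boundary).bounds
    return int(math.ceil(maxy)) + 2, int(math.ceil(maxx)) + 2


def normalized_depth_field(
    geometry: UterusSectionGeometry, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Normalised depth d in [0, 1] at every myometrial pixel center,
    NaN outside the wall.

    Distances are exact Euclidean point-to-boundary distances (to the
    polygon rings), evaluated at pixel centers, so discretisation error
    comes only from the pixel grid itself.
    """
    if shape is None:
        shape = _raster_shape(geometry)
    wall = _myometrium_mask(geometry, shape)
    inner_ring = LinearRing(geometry.inner_boundary)
    outer_ring = LinearRing(geometry.outer_boundary)
    rr, cc = np.nonzero(wall)
    pts = shapely.points(cc.astype(float), rr.astype(float))
    din = shapely.distance(pts, inner_ring)
    dout = shapely.distance(pts, outer_ring)
    depth = np.full(shape, np.nan)
    denom = din + dout
    denom[denom == 0] = np.inf
    depth[rr, cc] = din / denom
    return depth


def _myometrium_mask(
    geometry: UterusSectionGeometry, shape: tuple[int, int]
) -> np.ndarray:
    outer = rasterize_polygons([geometry.outer_boundary], shape)
    inner = rasterize_polygons([geometry.inner_boundary], shape)
    return outer & ~inner


def assign_grade(
    geometry: UterusSectionGeometry,
    mouse_id: str = "",
    shape: tuple[int, int] | None = None,
) -> GradeResult:
    """Grade one uterus by the deepest focus pixel.

    Grade I when 0 < d_max <= 1/3, II when d_max <= 2/3, III beyond
    (closed upper bounds, mirroring the inner-third / two-thirds
    wording). Foci entirely outside the wall are ignored with a warning.
    """
    if shape is None:
        shape = _raster_shape(geometry)
    if not geometry.foci:
        return GradeResult(mouse_id, math.nan, "0", False)
    depth = normalized_depth_field(geometry, shape)
    wall = ~np.isnan(depth)
    d_max = -math.inf
    any_inside = False
    for i, focus in enumerate(geometry.foci):
        fmask = rasterize_polygons([focus], shape) & wall
        if not fmask.any():
            warnings.warn(
                f"focus {i} lies entirely outside the myometrium; ignored",
                stacklevel=2,
            )
            continue
        any_inside = True
        d_max = max(d_max, float(np.nanmax(depth[fmask])))
    if not any_inside:
        return GradeResult(mouse_id, math.nan, "0", False)
    if d_max <= 1 / 3:
        grade = "I"
    elif d_max <= 2 / 3:
        grade = "II"
    else:
        grade = "III"
    return GradeResult(mouse_id, d_max, grade, True)


def cohort_grade_distribution(
    grades: Sequence[GradeResult | str],
) -> dict[str, float]:
    """Per-grade cohort percentages plus the invasion share (grade >= I).

    Percentages are rounded half-up to two decimals from the exact
    integer ratios. Accepts GradeResults or bare grade labels.
    """
    labels = [g.grade if isinstance(g, GradeResult) else str(g) for g in grades]
    if not labels:
        raise ValueError("empty cohort")
    unknown = set(labels) - set(GRADES)
    if unknown:
        raise ValueError(f"unknown grade labels: {sorted(unknown)}")
    n = len(labels)
    out = {g: percent_half_up(labels.count(g), n) for g in GRADES}
    out["invasion"] = percent_half_up(sum(l != "0" for l in labels), n)
    return out
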
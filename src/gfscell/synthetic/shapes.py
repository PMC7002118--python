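"""Parametric cell-shape families and their extreme-point annotations.

Four boundary-polygon families cover the morphologies seen in diagnostic
microscopy: *ellipse* (round mammalian nucleus), *crescent* (arc-shaped
*Toxoplasma* tachyzoite), *spindle* (elongated *Trypanosoma* trypomastigote)
and *pear* (pyriform intraerythrocytic *Babesia*).  Each family is an exact
geometric construction — ellipse by its parametric curve, crescent as the
boolean difference of two discs, spindle as two symmetric circular arcs
meeting at sharp tips, pear as the outer-tangent hull of two unequal discs —
rotated and translated into place.

Extreme points (topmost/leftmost/bottommost/rightmost boundary vertices, in
image convention with y increasing downward) are read off the polygon, the
same way annotations are derived from segmentation masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as sgeom
from shapely import affinity

from ..errors import DegenerateShapeError, InvalidParameterError
from ..keypoints import ExtremeSet

FAMILIES = ("ellipse", "crescent", "spindle", "pear")


@dataclass(frozen=True)
class ShapeSpec:
    """One cell instance: family, center (pixels), size parameters, orientation.

    Size parameters by family (all pixels, all > 0):

    - ellipse:  ``a`` (semi-major), ``b`` (semi-minor)
    - crescent: ``outer_radius``, ``inner_radius``, ``offset`` (distance of
      the subtracted disc's center from the outer disc's center)
    - spindle:  ``length`` (tip to tip), ``width`` (maximal thickness)
    - pear:     ``big_radius``, ``small_radius``, ``separation`` (distance
      between the two disc centers)
    """

    family: str
    center: tuple[float, float] = (0.0, 0.0)
    params: dict = field(default_factory=dict)
    orientation: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidParameterError(f"unknown shape family {self.family!r}")
        if not (0.0 <= self.orientation < 2 * math.pi):
            object.__setattr__(self, "orientation", self.orientation % (2 * math.pi))
        for k, v in self.params.items():
            if v <= 0:
                raise InvalidParameterError(f"{self.family} parameter {k}={v} must be > 0")

    def nominal_radius(self) -> float:
        """Half the larger overall extent; used for collision-ish placement."""
        p = self.params
        if self.family == "ellipse":
            return max(p["a"], p["b"])
        if self.family == "crescent":
            return p["outer_radius"]
        if self.family == "spindle":
            return p["length"] / 2.0
        return (p["separation"] + p["big_radius"] + p["small_radius"]) / 2.0


def _circle(center, radius, n) -> sgeom.Polygon:
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return sgeom.Polygon(np.c_[center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def _resample_ring(coords: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed ring to n evenly spaced (by arc length) vertices."""
    ring = sgeom.LinearRing(coords)
    dists = np.linspace(0.0, ring.length, n, endpoint=False)
    return np.array([ring.interpolate(d).coords[0] for d in dists])


def _ellipse_local(a: float, b: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return np.c_[a * np.cos(t), b * np.sin(t)]


def _crescent_local(outer_radius: float, inner_radius: float, offset: float, n: int) -> np.ndarray:
    outer = _circle((0.0, 0.0), outer_radius, max(n, 64))
    inner = _circle((offset, 0.0), inner_radius, max(n, 64))
    diff = outer.difference(inner)
    if diff.is_empty:
        raise InvalidParameterError("inner disc swallows the outer disc entirely")
    if diff.geom_type == "MultiPolygon":  # keep the dominant lobe
        diff = max(diff.geoms, key=lambda g: g.area)
    return _resample_ring(np.asarray(diff.exterior.coords[:-1]), n)


def _spindle_local(length: float, width: float, n: int) -> np.ndarray:
    """Two circular arcs through the tips (±L/2, 0) and the bulge (0, ±w/2)."""
    if width >= length:
        raise InvalidParameterError("spindle width must be smaller than its length")
    L, w = length, width
    c = (w * w - L * L) / (4.0 * w)  # center of the upper arc (on the −y side)
    R = w / 2.0 - c
    th_right = math.atan2(0.0 - c, L / 2.0)
    th_left = math.atan2(0.0 - c, -L / 2.0)
    m = n // 2
    t_up = np.linspace(th_right, th_left, m + 1)  # both tips are exact vertices
    upper = np.c_[R * np.cos(t_up), c + R * np.sin(t_up)]
    t_low = np.linspace(th_left, th_right, n - m + 1)[1:-1]  # interior only
    lower = np.c_[R * np.cos(t_low), -(c + R * np.sin(t_low))]
    return np.vstack([upper, lower])


def _pear_local(big_radius: float, small_radius: float, separation: float, n: int) -> np.ndarray:
    """Union of two discs bridged by their outer tangents (convex hull)."""
    big = _circle((0.0, 0.0), big_radius, max(n, 64))
    small = _circle((separation, 0.0), small_radius, max(n, 64))
    hull = big.union(small).convex_hull
    coords = _resample_ring(np.asarray(hull.exterior.coords[:-1]), n)
    # recenter on the midpoint of the overall x-extent so rotation is tidy
    coords[:, 0] -= (coords[:, 0].min() + coords[:, 0].max()) / 2.0
    return coords


_BUILDERS = {
    "ellipse": lambda p, n: _ellipse_local(p["a"], p["b"], n),
    "crescent": lambda p, n: _crescent_local(p["outer_radius"], p["inner_radius"], p["offset"], n),
    "spindle": lambda p, n: _spindle_local(p["length"], p["width"], n),
    "pear": lambda p, n: _pear_local(p["big_radius"], p["small_radius"], p["separation"], n),
}


def make_shape(spec: ShapeSpec, n_vertices: int = 64) -> np.ndarray:
    """Closed boundary polygon of a shape, as an (n_vertices, 2) array.

    The polygon is built in a local frame, rotated by ``spec.orientation``
    and translated to ``spec.center``.  Vertices are ordered along the
    boundary; the polygon is simple (non-self-intersecting).
    """
    if n_vertices < 16:
        raise InvalidParameterError("n_vertices must be >= 16")
    local = _BUILDERS[spec.family](spec.params, n_vertices)
    c, s = math.cos(spec.orientation), math.sin(spec.orientation)
    rot = np.array([[c, -s], [s, c]])
    return local @ rot.T + np.asarray(spec.center, dtype=float)


def extreme_points(polygon: np.ndarray) -> ExtremeSet:
    """Extreme points of a polygon in image convention (y downward).

    top = vertex of minimal y, bottom = maximal y, left = minimal x,
    right = maximal x; the center is the midpoint
    ((left.x + right.x)/2, (top.y + bottom.y)/2).  Ties are broken by the
    first vertex in boundary order.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise DegenerateShapeError("polygon needs at least 3 two-dimensional vertices")
    # collinearity check via the maximal cross-product magnitude
    v0 = poly[0]
    d = poly - v0
    cross = np.abs(d[:, 0, None] * d[None, :, 1] - d[:, 1, None] * d[None, :, 0])
    if cross.max() < 1e-12:
        raise DegenerateShapeError("all polygon vertices are collinear")

    top = tuple(poly[np.argmin(poly[:, 1])])
    bottom = tuple(poly[np.argmax(poly[:, 1])])
    left = tuple(poly[np.argmin(poly[:, 0])])
    right = tuple(poly[np.argmax(poly[:, 0])])
    return ExtremeSet(top=top, left=left, bottom=bottom, right=right)
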
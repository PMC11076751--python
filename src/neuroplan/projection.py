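"""Planar geometry kernel.

Every accuracy metric is defined on a single orthographic *assessment plane*:
the plane through the tumor centroid whose normal is the phantom's projection
axis. Meshes are reduced to their silhouette (the outline of the orthographic
shadow) on this plane; participant drawings made on the scalp or bone layer
are orthographically projected into the same plane. All coordinates are mm.

Regions are shapely ``Polygon``/``MultiPolygon`` objects, polylines are open
shapely ``LineString`` objects, and craniotomies are :class:`Quad2D` simple
quadrilaterals. Areas and intersections use exact polygon clipping; a
rasterized area estimate (:func:`raster_area`) is provided as an independent
cross-check of the exact engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import shapely
import trimesh
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .errors import (
    GeometryError,
    InvalidInputError,
    OffSurfaceError,
    UndefinedMarginError,
)

__all__ = [
    "AssessmentPlane",
    "Quad2D",
    "ellipse_region",
    "as_region",
    "make_polyline",
    "project_silhouette",
    "project_drawing",
    "lift_to_surface",
    "area",
    "raster_area",
    "intersection_area",
    "min_distance",
    "centroid",
    "edge_margin",
    "quad_margins",
]

MARGIN_CONVENTIONS = ("midpoint-ray", "segment-min")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise GeometryError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class AssessmentPlane:
    """Orthographic projection plane with a deterministic in-plane basis."""

    origin: np.ndarray
    axis: np.ndarray
    u: np.ndarray = field(default=None)  # type: ignore[assignment]
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        axis = _unit(self.axis)
        object.__setattr__(self, "axis", axis)
        if self.u is None:
            helper = np.array([1.0, 0.0, 0.0])
            if abs(axis @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            u = _unit(helper - (helper @ axis) * axis)
            object.__setattr__(self, "u", u)
            object.__setattr__(self, "v", np.cross(axis, u))
        else:
            u = np.asarray(self.u, dtype=float)
            v = np.asarray(self.v, dtype=float)
            if not (
                np.allclose([u @ u, v @ v], 1.0, atol=1e-9)
                and abs(u @ v) < 1e-9
                and abs(u @ axis) < 1e-9
                and abs(v @ axis) < 1e-9
            ):
                raise GeometryError("plane basis must be orthonormal and orthogonal to axis")
            object.__setattr__(self, "u", u)
            object.__setattr__(self, "v", v)

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """World (n,3) mm -> plane (n,2) mm (orthographic)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.column_stack([p @ self.u, p @ self.v])

    def to_world(self, points2d: np.ndarray, height: float = 0.0) -> np.ndarray:
        """Plane (n,2) mm -> world (n,3) mm at signed ``height`` along the axis."""
        q = np.atleast_2d(np.asarray(points2d, dtype=float))
        return self.origin + np.outer(q[:, 0], self.u) + np.outer(q[:, 1], self.v) + height * self.axis


@dataclass(frozen=True)
class Quad2D:
    """Simple quadrilateral in plane coordinates; edges indexed 0-3."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (4, 2) or not np.all(np.isfinite(v)):
            raise InvalidInputError("Quad2D requires 4 finite 2D vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("quadrilateral must be simple with positive area")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def edge(self, i: int) -> np.ndarray:
        return np.array([self.vertices[i % 4], self.vertices[(i + 1) % 4]])

    def edges(self) -> Iterable[np.ndarray]:
        return (self.edge(i) for i in range(4))


def ellipse_region(a: float, b: float, center=(0.0, 0.0), angle: float = 0.0, n: int = 256) -> Polygon:
    """Polygonal ellipse with semi-axes a, b (mm), optionally rotated (radians)."""
    if a <= 0 or b <= 0:
        raise GeometryError("ellipse semi-axes must be positive")
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    return Polygon(np.column_stack([center[0] + c * x - s * y, center[1] + s * x + c * y]))


def as_region(obj) -> BaseGeometry:
    """Validate a planar region (Polygon/MultiPolygon or outer ring coordinates)."""
    if isinstance(obj, BaseGeometry):
        geom = obj
    else:
        coords = np.asarray(obj, dtype=float)
        if coords.ndim != 2 or coords.shape[0] < 3 or not np.all(np.isfinite(coords)):
            raise GeometryError("region ring needs >= 3 finite 2D vertices")
        geom = Polygon(coords)
    if geom.is_empty:
        return geom
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise GeometryError(f"not a region: {geom.geom_type}")
    if not geom.is_valid:
        raise GeometryError("invalid region (self-intersecting or malformed ring)")
    return geom


def make_polyline(coords) -> LineString:
    """Validate an open polyline from an (n,2) coordinate list."""
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InvalidInputError("polyline needs >= 2 two-dimensional vertices")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("polyline coordinates must be finite")
    return LineString(pts)


# ---------------------------------------------------------------------------
# projection


def project_silhouette(mesh: trimesh.Trimesh, plane: AssessmentPlane) -> Polygon:
    """Outline of the mesh's orthographic shadow on the assessment plane.

    Convex meshes reduce to the convex hull of their projected vertices
    (exact); general meshes use the union of all projected triangles.
    """
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise GeometryError("silhouette requires a non-empty triangle mesh")
    pts = plane.to_plane(mesh.vertices)
    if mesh.is_convex:
        hull = MultiPoint(pts).convex_hull
        if hull.geom_type != "Polygon":
            raise GeometryError("degenerate mesh: projection collapses to a line")
        return hull
    tris = shapely.polygons(pts[mesh.faces])
    tris = shapely.make_valid(tris)
    merged = shapely.union_all(tris)
    merged = shapely.make_valid(merged)
    if merged.is_empty or merged.area == 0:
        raise GeometryError("degenerate mesh: zero-area shadow")
    if merged.geom_type == "GeometryCollection":
        polys = [g for g in merged.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        merged = shapely.union_all(polys)
    return merged


def project_drawing(
    points: np.ndarray,
    layer_mesh: trimesh.Trimesh,
    plane: AssessmentPlane,
    kind: str,
    tol: float = 1.5,
):
    """Project an on-surface drawing into the assessment plane.

    ``kind`` is one of ``region`` (closed painted ring), ``polyline`` (open
    incision), ``quad`` (craniotomy), ``points`` (burr holes). Points farther
    than ``tol`` mm from the layer mesh are rejected.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise InvalidInputError("drawing points must be 3D world coordinates")
    if kind == "polyline" and pts.shape[0] < 2:
        raise InvalidInputError("polyline drawing needs >= 2 points")
    _, dist, _ = trimesh.proximity.closest_point_naive(layer_mesh, pts)
    if np.any(dist > tol):
        worst = float(np.max(dist))
        raise OffSurfaceError(f"drawing point {worst:.2f} mm off the layer surface (tol {tol} mm)")
    flat = plane.to_plane(pts)
    if kind == "region":
        return as_region(flat)
    if kind == "polyline":
        return make_polyline(flat)
    if kind == "quad":
        if flat.shape[0] != 4:
            raise InvalidInputError("craniotomy drawing needs exactly 4 points")
        return Quad2D(flat)
    if kind == "points":
        return flat
    raise InvalidInputError(f"unknown drawing kind: {kind!r}")


def lift_to_surface(
    mesh: trimesh.Trimesh, plane: AssessmentPlane, points2d: np.ndarray, clearance: float = 500.0
) -> np.ndarray:
    """Map plane points back onto the outer mesh surface along the plane axis.

    Casts rays antiparallel to the projection axis from ``clearance`` mm
    above; returns the outermost hit per point. Points whose ray misses the
    mesh raise :class:`OffSurfaceError`.
    """
    pts2d = np.atleast_2d(np.asarray(points2d, dtype=float))
    origins = plane.to_world(pts2d, height=clearance)
    d = -plane.axis
    tri = mesh.triangles  # (n, 3, 3)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    out = np.full((len(pts2d), 3), np.nan)
    for i, o in enumerate(origins):
        # Moller-Trumbore over all triangles (meshes here are small)
        s = o - tri[:, 0]
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), np.nan)
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", e2, q)
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
        if np.any(hit):
            out[i] = o + d * np.min(t[hit])  # outermost surface point
    if np.any(np.isnan(out)):
        raise OffSurfaceError("a plane point does not project onto the mesh surface")
    return out


# ---------------------------------------------------------------------------
# measures


def area(region) -> float:
    """Region area in mm² (exact polygon area)."""
    return float(as_region(region).area)


def raster_area(region, pitch: float = 0.25) -> float:
    """Rasterized area estimate: count of cell centers inside, times pitch².

    Independent cross-check of the exact engine; error is bounded by
    pitch × perimeter.
    """
    geom = as_region(region)
    if geom.is_empty:
        return 0.0
    minx, miny, maxx, maxy = geom.bounds
    xs = np.arange(minx + pitch / 2, maxx, pitch)
    ys = np.arange(miny + pitch / 2, maxy, pitch)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    return float(inside.sum()) * pitch * pitch


def intersection_area(a, b) -> float:
    """Area of overlap between two regions (mm²)."""
    ga, gb = as_region(a), as_region(b)
    return float(ga.intersection(gb).area)


def min_distance(point, line: LineString) -> float:
    """Euclidean minimum distance (mm) from a point to an open polyline."""
    if not isinstance(line, LineString):
        line = make_polyline(line)
    if line.is_empty or len(line.coords) < 2:
        raise InvalidInputError("polyline needs >= 2 vertices")
    p = np.asarray(point, dtype=float).ravel()
    return float(Point(p).distance(line))


def centroid(region) -> np.ndarray:
    """Area centroid of a region; the tumor 'epicenter' when applied to the silhouette."""
    geom = as_region(region)
    if geom.is_empty or geom.area <= 0:
        raise GeometryError("centroid undefined for zero-area region")
    c = geom.centroid
    return np.array([c.x, c.y])


def _ray_boundary_distance(c: np.ndarray, d: np.ndarray, silhouette) -> float:
    """Distance from c to the outermost silhouette-boundary crossing along ray d."""
    geom = as_region(silhouette)
    minx, miny, maxx, maxy = geom.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny) + 1.0
    ray = LineString([c, c + d * reach])
    hit = ray.intersection(geom.boundary)
    ts = []
    for g in getattr(hit, "geoms", [hit]):
        if g.is_empty:
            continue
        coords = np.asarray(g.coords)
        ts.extend(coords @ d - c @ d)
    if not ts:
        raise UndefinedMarginError("centroid ray misses the silhouette boundary")
    return float(max(ts))


def edge_margin(edge, silhouette, convention: str = "midpoint-ray") -> float:
    """Signed margin (mm) between a craniotomy edge and the silhouette border.

    ``midpoint-ray`` (reference convention): along the ray from the
    silhouette centroid through the edge midpoint, the margin is the distance
    from the boundary crossing to the midpoint — positive when the midpoint
    lies outside the silhouette, negative inside. ``segment-min`` uses the
    minimum boundary-to-segment distance with the same sign rule.
    """
    if convention not in MARGIN_CONVENTIONS:
        raise InvalidInputError(f"unknown margin convention {convention!r}")
    e = np.asarray(edge, dtype=float)
    if e.shape != (2, 2) or not np.all(np.isfinite(e)):
        raise InvalidInputError("edge must be two finite 2D endpoints")
    geom = as_region(silhouette)
    if geom.area <= 0:
        raise GeometryError("silhouette must have positive area")
    c = centroid(geom)
    mid = e.mean(axis=0)
    if convention == "segment-min":
        dist = float(geom.boundary.distance(LineString(e)))
        sign = 1.0 if not geom.contains(Point(mid)) else -1.0
        return sign * dist
    v = mid - c
    t_mid = float(np.linalg.norm(v))
    if t_mid < 1e-9:
        # midpoint at the centroid: maximally interior
        d = _unit(e[1] - e[0])[::-1] * np.array([1.0, -1.0])
    else:
        d = v / t_mid
    t_boundary = _ray_boundary_distance(c, d, geom)
    return t_mid - t_boundary


def quad_margins(quad: Quad2D, silhouette, convention: str = "midpoint-ray") -> np.ndarray:
    """Signed margins of the four quadrilateral edges, indexed 0-3."""
    return np.array([edge_margin(quad.edge(i), silhouette, convention) for i in range(4)])
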
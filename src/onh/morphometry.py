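"""ONH structural measures from segmented OCT surfaces.

Implements the four measures used to track pressure-induced optic nerve head
remodelling:

* **BMO reference plane** -- orthogonal least-squares plane through the
  Bruch's membrane opening ring, normal oriented posteriorly.
* **BMO area** -- shoelace area of the ring projected into that plane (mm^2).
* **mean LCD** -- mean signed perpendicular distance from the plane to the
  delineated anterior lamina cribrosa nodes projecting inside the BMO
  polygon (positive = posterior, i.e. deeper).
* **mean MRW** -- per BMO point, the minimum Euclidean distance to the
  triangulated ILM, restricted to triangles whose centroid projects inside
  the BMO polygon (the neuroretinal-rim constraint).
* **LC visibility** -- percentage of the enface BMO polygon covered by
  delineated LC grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import (
    DegenerateGeometryError,
    EmptyLCError,
    GeometryError,
    RimConstraintError,
)
from .volume import SegmentedONHVolume

__all__ = [
    "BMOReferencePlane",
    "MorphometryResult",
    "fit_bmo_plane",
    "compute_bmo_area",
    "compute_lcd",
    "lcd_from_points",
    "compute_mrw",
    "mrw_from_mesh",
    "compute_lc_visibility",
    "measure_volume",
    "point_triangle_distance",
]

_MISSING_ILM_WARN_FRACTION = 0.25


@dataclass(frozen=True)
class BMOReferencePlane:
    """Best-fit plane through the BMO ring (um coordinates).

    ``normal`` is a unit vector oriented so that positive signed distance
    means posterior (deeper); ``basis`` holds two orthonormal in-plane
    directions used for 2D projections.
    """

    centroid: np.ndarray
    normal: np.ndarray
    rms_fit_residual: float
    basis: np.ndarray  # (2, 3)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.centroid) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        """In-plane (u, v) coordinates of the orthogonal projections."""
        return (np.atleast_2d(points) - self.centroid) @ self.basis.T


@dataclass(frozen=True)
class MorphometryResult:
    mean_mrw: float  # um
    mean_lcd: float  # um
    bmo_area: float  # mm^2
    lc_visibility: float  # percent
    n_bmo_points: int
    n_lcd_samples: int
    warnings: tuple[str, ...] = field(default=())


def fit_bmo_plane(bmo_points: np.ndarray) -> BMOReferencePlane:
    """Orthogonal least-squares plane through the BMO points.

    Minimizes the sum of squared perpendicular distances (total least
    squares via SVD).  The normal is oriented toward +z (posterior); for a
    normal with zero z component the tie is broken toward +y, then +x.
    """
    pts = np.asarray(bmo_points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("BMO points are collinear; no unique plane")
    normal = vt[2]
    key = (normal[2], normal[1], normal[0])
    if key < (0.0, 0.0, 0.0):
        normal = -normal
    residuals = centered @ normal
    return BMOReferencePlane(
        centroid=centroid,
        normal=normal / np.linalg.norm(normal),
        rms_fit_residual=float(np.sqrt(np.mean(residuals**2))),
        basis=vt[:2].copy(),
    )


def _bmo_polygon(bmo_points: np.ndarray, plane: BMOReferencePlane) -> Polygon:
    """Projected BMO ring as a shapely polygon, vertices ordered by angle."""
    uv = plane.project(np.asarray(bmo_points, float))
    order = np.argsort(np.arctan2(uv[:, 1] - uv[:, 1].mean(), uv[:, 0] - uv[:, 0].mean()))
    poly = Polygon(uv[order])
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("projected BMO ring is self-intersecting or degenerate")
    return poly


def _covers_xy(poly: Polygon, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Boundary-inclusive point-in-polygon test (on-boundary counts inside)."""
    return shapely.intersects_xy(poly, u, v)


def compute_bmo_area(bmo_points: np.ndarray, plane: BMOReferencePlane) -> float:
    """Polygon area of the projected BMO ring, in mm^2."""
    return float(_bmo_polygon(bmo_points, plane).area * 1e-6)


def compute_lcd(
    volume: SegmentedONHVolume, plane: BMOReferencePlane
) -> tuple[float, int]:
    """Mean signed perpendicular BMO-plane -> anterior-LC distance.

    Averages over every delineated LC node whose projection onto the plane
    lies inside the BMO polygon (boundary-inclusive).  Positive = posterior;
    anterior excursions contribute negative distances.
    """
    return lcd_from_points(volume.surface_points("lc"), volume.bmo_points, plane)


def lcd_from_points(
    lc_points: np.ndarray, bmo_points: np.ndarray, plane: BMOReferencePlane
) -> tuple[float, int]:
    """LCD core operating on bare 3D LC points (see :func:`compute_lcd`)."""
    poly = _bmo_polygon(bmo_points, plane)
    pts = np.atleast_2d(np.asarray(lc_points, float))
    if pts.size == 0:
        raise EmptyLCError("no delineated LC nodes in the volume")
    uv = plane.project(pts)
    inside = _covers_xy(poly, uv[:, 0], uv[:, 1])
    if not inside.any():
        raise EmptyLCError("no delineated LC node projects inside the BMO polygon")
    d = plane.signed_distance(pts[inside])
    return float(d.mean()), int(inside.sum())


def point_triangle_distance(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Exact distances from point ``p`` to triangles ``(a[i], b[i], c[i])``.

    Vectorized closest-point classification over the seven Voronoi regions of
    each triangle (vertices, edges, face); no approximation.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    c = np.atleast_2d(c)
    ab = b - a
    ac = c - a
    ap = p - a
    bp = p - b
    cp = p - c
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    closest = np.empty_like(a)
    done = np.zeros(len(a), bool)

    def assign(mask: np.ndarray, value: np.ndarray) -> None:
        sel = mask & ~done
        closest[sel] = value[sel]
        done[sel] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)
        denom_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        assign(
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            b + t_bc[:, None] * (c - b),
        )
        denom = va + vb + vc
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        assign(np.ones(len(a), bool), a + v[:, None] * ab + w[:, None] * ac)

    return np.linalg.norm(p - closest, axis=1)


def ilm_triangles(volume: SegmentedONHVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two triangles per grid cell, skipping cells with any missing corner."""
    g = volume.geometry
    z = volume.ilm_height
    xs, ys = g.node_grid()
    pts = np.dstack([xs, ys, z])
    p00 = pts[:-1, :-1].reshape(-1, 3)
    p01 = pts[:-1, 1:].reshape(-1, 3)
    p10 = pts[1:, :-1].reshape(-1, 3)
    p11 = pts[1:, 1:].reshape(-1, 3)
    ok = np.isfinite(p00[:, 2]) & np.isfinite(p01[:, 2]) & np.isfinite(p10[:, 2]) & np.isfinite(p11[:, 2])
    a = np.concatenate([p00[ok], p11[ok]])
    b = np.concatenate([p01[ok], p10[ok]])
    c = np.concatenate([p10[ok], p01[ok]])
    return a, b, c


def compute_mrw(
    volume: SegmentedONHVolume,
    bmo_points: np.ndarray | None = None,
    plane: BMOReferencePlane | None = None,
) -> tuple[float, np.ndarray]:
    """Mean and per-point minimum rim width.

    For each BMO point, the minimum Euclidean point-to-triangle distance
    over admissible ILM triangles; a triangle is admissible when its
    centroid projects inside the BMO polygon, which keeps the measurement
    within the neuroretinal rim.
    """
    bmo = np.asarray(bmo_points if bmo_points is not None else volume.bmo_points, float)
    return mrw_from_mesh(bmo, ilm_triangles(volume), plane)


def mrw_from_mesh(
    bmo_points: np.ndarray,
    triangles: tuple[np.ndarray, np.ndarray, np.ndarray],
    plane: BMOReferencePlane | None = None,
) -> tuple[float, np.ndarray]:
    """MRW core operating on a bare triangle soup (see :func:`compute_mrw`)."""
    bmo = np.asarray(bmo_points, float)
    plane = plane or fit_bmo_plane(bmo)
    poly = _bmo_polygon(bmo, plane)
    a, b, c = triangles
    if len(a) == 0:
        raise RimConstraintError("ILM grid has no fully delineated cells")
    centroids = (a + b + c) / 3.0
    uv = plane.project(centroids)
    admissible = _covers_xy(poly, uv[:, 0], uv[:, 1])
    if not admissible.any():
        raise RimConstraintError(
            f"no admissible ILM triangle for BMO point 0 at {tuple(bmo[0])}"
        )
    a, b, c = a[admissible], b[admissible], c[admissible]

    per_point = np.array([point_triangle_distance(p, a, b, c).min() for p in bmo])
    return float(per_point.mean()), per_point


def compute_lc_visibility(
    volume: SegmentedONHVolume, plane: BMOReferencePlane
) -> float:
    """LC visibility as a percentage of the enface BMO area.

    Rasterizes the enface (lateral-projection) BMO polygon on the lateral
    grid using cell-centre inclusion; each in-polygon cell contributes the
    fraction of its four corner LC nodes that are delineated, which keeps
    cells cut by a shadow edge from being counted all-or-nothing.
    """
    bmo = volume.bmo_points
    xy = bmo[:, :2]
    order = np.argsort(np.arctan2(xy[:, 1] - xy[:, 1].mean(), xy[:, 0] - xy[:, 0].mean()))
    poly = Polygon(xy[order])
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("enface BMO polygon is degenerate")

    g = volume.geometry
    lc_ok = np.isfinite(volume.lc_height)
    corner_frac = (
        lc_ok[:-1, :-1].astype(float)
        + lc_ok[:-1, 1:]
        + lc_ok[1:, :-1]
        + lc_ok[1:, 1:]
    ) / 4.0
    cx = (np.arange(g.n_ascans - 1) + 0.5) * g.ascan_spacing
    cy = (np.arange(g.n_bscans - 1) + 0.5) * g.bscan_spacing
    gx, gy = np.meshgrid(cx, cy)
    inside = _covers_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    cell_area = g.ascan_spacing * g.bscan_spacing
    visible_area = float((corner_frac * inside).sum()) * cell_area
    return float(np.clip(100.0 * visible_area / poly.area, 0.0, 100.0))


def measure_volume(volume: SegmentedONHVolume) -> MorphometryResult:
    """Run the full morphometry chain on one volume."""
    plane = fit_bmo_plane(volume.bmo_points)
    area = compute_bmo_area(volume.bmo_points, plane)
    mean_lcd, n_lcd = compute_lcd(volume, plane)
    mean_mrw, _ = compute_mrw(volume, volume.bmo_points, plane)
    visibility = compute_lc_visibility(volume, plane)

    warnings: list[str] = []
    poly = _bmo_polygon(volume.bmo_points, plane)
    xs, ys = volume.geometry.node_grid()
    # missing-ILM check over nodes whose lateral position falls within the BMO
    uv_lat = plane.project(
        np.column_stack([xs.ravel(), ys.ravel(), np.full(xs.size, plane.centroid[2])])
    )
    in_bmo = _covers_xy(poly, uv_lat[:, 0], uv_lat[:, 1])
    if in_bmo.any():
        frac = float((~np.isfinite(volume.ilm_height.ravel()[in_bmo])).mean())
        if frac > _MISSING_ILM_WARN_FRACTION:
            warnings.append(
                f"{frac:.0%} of within-BMO ILM nodes are missing; MRW may be biased"
            )

    return MorphometryResult(
        mean_mrw=mean_mrw,
        mean_lcd=mean_lcd,
        bmo_area=area,
        lc_visibility=visibility,
        n_bmo_points=int(len(volume.bmo_points)),
        n_lcd_samples=n_lcd,
        warnings=tuple(warnings),
    )
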
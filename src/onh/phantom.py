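"""Analytic ONH phantoms with known morphometry.

A phantom stands in for a manually delineated OCT volume: an elliptical BMO
ring lying exactly in a (possibly tilted) plane, a smooth rim+cup ILM
surface, and an anterior-LC surface at a prescribed perpendicular depth from
the BMO plane, with an optional contiguous "shadow" wedge of missing LC
nodes.  Because every surface is defined as a perpendicular-offset field
from the BMO plane, the four target measures -- BMO area, mean lamina
cribrosa depth (LCD), mean minimum rim width (MRW) and LC visibility -- have
closed-form ground truth wherever the geometry is flat, and a dense
brute-force value otherwise.

Surface construction.  Let the BMO plane be tilted by ``theta`` about the
x (A-scan) axis through the field centre ``c``; its unit normal is
``n = (0, -sin theta, cos theta)`` (posterior-positive).  A surface with a
prescribed signed perpendicular distance field ``D(x, y)`` is stored on the
lateral grid as::

    z(x, y) = z_plane(x, y) + D(x, y) / cos(theta)

since the signed distance of ``(x, y, z)`` to the plane is
``(z - z_plane(x, y)) * cos(theta)``.  The ILM uses
``D = -rim_height + cup_depth * (1 + cos(pi * rho)) / 2`` inside the BMO
(``rho`` is the normalized elliptical radius of the enface projection), the
LC uses ``D = lc_depth`` (flat), a small in-plane gradient (tilted), or
``D = lc_depth + sag * (1 - rho^2)`` (bowl).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, ParameterError
from .volume import ScanGeometry, SegmentedONHVolume

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "make_phantom_volume",
    "mrw_point_cloud_oracle",
    "lcd_integration_oracle",
]

LC_SHAPES = ("flat", "tilted", "bowl")


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic ONH (lengths in um, angles in degrees).

    ``lc_outer_margin`` extends the delineated LC slightly beyond the BMO
    (normalized radius 1.15), mimicking the LC insertion into the
    peripapillary sclera; ``lc_visible_fraction`` of the delineated LC is
    kept, the rest removed as one contiguous angular wedge (shadowing).
    """

    bmo_semi_axis_major: float = 950.0
    bmo_semi_axis_minor: float = 885.0
    bmo_tilt_deg: float = 0.0
    rim_height: float = 280.0
    cup_depth: float = 0.0
    lc_depth: float = 203.0
    lc_shape: str = "flat"
    lc_tilt_deg: float = 3.0
    lc_bowl_sag: float = 60.0
    surface_noise_sd: float = 0.0
    lc_visible_fraction: float = 0.9
    lc_outer_margin: float = 1.15
    n_bmo_points: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bmo_semi_axis_major <= 0 or self.bmo_semi_axis_minor <= 0:
            raise ParameterError("BMO semi-axes must be positive")
        if not 0.0 <= self.lc_visible_fraction <= 1.0:
            raise ParameterError("lc_visible_fraction must lie in [0, 1]")
        if self.surface_noise_sd < 0:
            raise ParameterError("surface noise SD must be >= 0")
        if self.lc_shape not in LC_SHAPES:
            raise ParameterError(f"lc_shape must be one of {LC_SHAPES}")
        if self.rim_height < 0 or self.cup_depth < 0:
            raise ParameterError("rim_height and cup_depth must be >= 0")
        if not -60.0 < self.bmo_tilt_deg < 60.0:
            raise ParameterError("bmo_tilt_deg outside the supported range")
        if self.n_bmo_points < 8:
            raise ParameterError("need at least 8 BMO ring points")
        if self.lc_outer_margin < 1.0:
            raise ParameterError("lc_outer_margin must be >= 1")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic (or densely integrated) morphometry of a phantom."""

    true_mean_mrw: float  # um
    true_mean_lcd: float  # um
    true_bmo_area: float  # mm^2
    true_lc_visibility: float  # percent


class _Frame:
    """Geometry of the phantom's BMO plane in the scan frame."""

    def __init__(self, params: PhantomParams, geometry: ScanGeometry):
        self.a = params.bmo_semi_axis_major
        self.b = params.bmo_semi_axis_minor
        self.theta = math.radians(params.bmo_tilt_deg)
        wx, wy = geometry.field_extent
        self.xc, self.yc, self.zc = wx / 2.0, wy / 2.0, 0.0
        self.cos_t = math.cos(self.theta)
        self.tan_t = math.tan(self.theta)
        # enface (lateral-projection) semi-axes of the tilted BMO ellipse
        self.ax_enface = self.a
        self.by_enface = self.b * self.cos_t
        if (
            self.ax_enface * params.lc_outer_margin > self.xc
            or self.by_enface * params.lc_outer_margin > self.yc
        ):
            raise GeometryError(
                "BMO ellipse (plus LC margin) exceeds the scanned field; "
                "shrink the semi-axes or enlarge the scan"
            )

    def plane_z(self, y: np.ndarray) -> np.ndarray:
        return self.zc + (y - self.yc) * self.tan_t

    def rho(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.hypot((x - self.xc) / self.ax_enface, (y - self.yc) / self.by_enface)

    def offset_to_z(self, y: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Height grid of a surface with perpendicular-offset field ``d``."""
        return self.plane_z(y) + d / self.cos_t

    def inplane_angle(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Elliptic parametric angle of the in-plane projection, in [0, 2pi)."""
        u = x - self.xc
        v = (y - self.yc) / self.cos_t
        return np.mod(np.arctan2(v / self.b, u / self.a), 2.0 * math.pi)

    def ring(self, n: int) -> np.ndarray:
        t = 2.0 * math.pi * np.arange(n) / n
        x = self.xc + self.a * np.cos(t)
        y = self.yc + self.b * np.sin(t) * self.cos_t
        z = self.zc + self.b * np.sin(t) * math.sin(self.theta)
        return np.column_stack([x, y, z])


def _ilm_offset(params: PhantomParams, rho: np.ndarray) -> np.ndarray:
    d = np.full(rho.shape, -params.rim_height, float)
    if params.cup_depth > 0:
        inside = rho < 1.0
        bump = 0.5 * (1.0 + np.cos(math.pi * rho[inside]))
        d[inside] += params.cup_depth * bump
    return d


def _lc_offset(
    params: PhantomParams, frame: _Frame, x: np.ndarray, y: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    if params.lc_shape == "flat":
        return np.full(rho.shape, params.lc_depth, float)
    if params.lc_shape == "tilted":
        lever = (y - frame.yc) / frame.cos_t  # in-plane v coordinate
        return params.lc_depth + math.tan(math.radians(params.lc_tilt_deg)) * lever
    # bowl: deepest at the centre, joining lc_depth at the BMO
    return params.lc_depth + params.lc_bowl_sag * np.clip(1.0 - rho**2, 0.0, None)


def _wedge_start(params: PhantomParams) -> float | None:
    """Angular origin of the missing-LC wedge, or None when fully visible.

    Drawn as the first variate of the phantom's seeded stream so the dense
    oracles can reproduce the same wedge independently of the grid.
    """
    if params.lc_visible_fraction >= 1.0:
        return None
    return float(np.random.default_rng(params.seed).uniform(0.0, 2.0 * math.pi))


def _wedge_mask(
    params: PhantomParams,
    frame: _Frame,
    x: np.ndarray,
    y: np.ndarray,
    t0: float | None,
) -> np.ndarray:
    """True where LC nodes are removed (invisible)."""
    if t0 is None:
        return np.zeros(np.shape(x), bool)
    frac_missing = 1.0 - params.lc_visible_fraction
    ang = np.mod(frame.inplane_angle(x, y) - t0, 2.0 * math.pi)
    return ang < 2.0 * math.pi * frac_missing


def _true_mean_lcd(params: PhantomParams, geometry: ScanGeometry) -> float:
    # Mean signed perpendicular distance over the visible part of the BMO
    # ellipse.  The flat and bowl profiles are angle-symmetric in normalized
    # coordinates, so the angular shadow wedge does not move their mean and
    # the closed forms hold; the tilted profile's mean depends on the
    # visible-domain centroid and is integrated densely instead.
    if params.lc_shape == "flat":
        return params.lc_depth
    if params.lc_shape == "bowl":
        # E[1 - rho^2] over the unit ellipse (any angular sector) is 1/2
        return params.lc_depth + params.lc_bowl_sag / 2.0
    if _wedge_start(params) is None:
        return params.lc_depth  # odd in-plane gradient averages out
    return lcd_integration_oracle(params, geometry)


def make_phantom_volume(
    params: PhantomParams, geometry: ScanGeometry | None = None
) -> tuple[SegmentedONHVolume, PhantomTruth]:
    """Build a phantom volume and its ground-truth morphometry.

    The BMO ring lies exactly on the parameterized (tilted) ellipse; surface
    noise, when requested, perturbs only the height grids, and the recorded
    truth always refers to the noise-free geometry.  Deterministic given
    ``params.seed``.
    """
    geometry = geometry or ScanGeometry()
    frame = _Frame(params, geometry)
    rng = np.random.default_rng(params.seed)

    xs, ys = geometry.node_grid()
    rho = frame.rho(xs, ys)

    ilm = frame.offset_to_z(ys, _ilm_offset(params, rho))
    lc = frame.offset_to_z(ys, _lc_offset(params, frame, xs, ys, rho))
    lc[rho > params.lc_outer_margin] = np.nan
    t0 = _wedge_start(params)
    if t0 is not None:
        rng.uniform(0.0, 2.0 * math.pi)  # consume the wedge draw from the stream
        lc[_wedge_mask(params, frame, xs, ys, t0) & (rho <= params.lc_outer_margin)] = np.nan

    if params.surface_noise_sd > 0:
        ilm = ilm + rng.normal(0.0, params.surface_noise_sd, ilm.shape)
        noisy_lc = lc + rng.normal(0.0, params.surface_noise_sd, lc.shape)
        lc = np.where(np.isfinite(lc), noisy_lc, np.nan)

    volume = SegmentedONHVolume(
        geometry=geometry,
        ilm_height=ilm,
        lc_height=lc,
        bmo_points=frame.ring(params.n_bmo_points),
        name=f"phantom-seed{params.seed}",
        meta={"kind": "phantom", "lc_shape": params.lc_shape},
    )

    if params.cup_depth == 0:
        true_mrw = params.rim_height
    else:
        true_mrw, _ = mrw_point_cloud_oracle(params, geometry)

    truth = PhantomTruth(
        true_mean_mrw=float(true_mrw),
        true_mean_lcd=float(_true_mean_lcd(params, geometry)),
        true_bmo_area=float(math.pi * params.bmo_semi_axis_major * params.bmo_semi_axis_minor * 1e-6),
        true_lc_visibility=float(100.0 * params.lc_visible_fraction),
    )
    return volume, truth


def _fine_axes(geometry: ScanGeometry, factor: int) -> tuple[np.ndarray, np.ndarray]:
    wx, wy = geometry.field_extent
    nx = (geometry.n_ascans - 1) * factor + 1
    ny = (geometry.n_bscans - 1) * factor + 1
    return np.linspace(0.0, wx, nx), np.linspace(0.0, wy, ny)


def mrw_point_cloud_oracle(
    params: PhantomParams,
    geometry: ScanGeometry | None = None,
    factor: int = 10,
    chunk: int = 262144,
) -> tuple[float, np.ndarray]:
    """Brute-force minimum rim width on a densely oversampled ILM point cloud.

    Samples the noise-free ILM at ``factor``-times the grid resolution, keeps
    only points whose enface projection falls inside the BMO ellipse (the rim
    constraint), and returns the mean and per-ring-point minimum Euclidean
    distance.  Independent of the triangulated estimator.
    """
    geometry = geometry or ScanGeometry()
    frame = _Frame(params, geometry)
    fx, fy = _fine_axes(geometry, factor)
    gx, gy = np.meshgrid(fx, fy)
    rho = frame.rho(gx, gy)
    gz = frame.offset_to_z(gy, _ilm_offset(params, rho))
    # rim constraint: keep samples whose in-plane projection onto the BMO
    # plane falls inside the BMO ellipse
    u = gx - frame.xc
    v = (gy - frame.yc) * frame.cos_t + (gz - frame.zc) * math.sin(frame.theta)
    keep = (u / frame.a) ** 2 + (v / frame.b) ** 2 <= 1.0
    pts = np.column_stack([gx[keep], gy[keep], gz[keep]])
    ring = frame.ring(params.n_bmo_points)
    per_point = np.empty(len(ring))
    for i, p in enumerate(ring):
        best = np.inf
        for start in range(0, len(pts), chunk):
            d2 = np.sum((pts[start : start + chunk] - p) ** 2, axis=1)
            best = min(best, float(d2.min()))
        per_point[i] = math.sqrt(best)
    return float(per_point.mean()), per_point


def lcd_integration_oracle(
    params: PhantomParams,
    geometry: ScanGeometry | None = None,
    factor: int = 10,
    respect_visibility: bool = True,
) -> float:
    """Mean perpendicular LC depth by dense integration over the BMO ellipse.

    By default integrates over the *visible* LC (excluding the phantom's
    shadow wedge), matching the domain the grid estimator averages over;
    pass ``respect_visibility=False`` for the full-ellipse mean.
    """
    geometry = geometry or ScanGeometry()
    frame = _Frame(params, geometry)
    fx, fy = _fine_axes(geometry, factor)
    gx, gy = np.meshgrid(fx, fy)
    rho = frame.rho(gx, gy)
    keep = rho <= 1.0
    if respect_visibility:
        t0 = _wedge_start(params)
        if t0 is not None:
            keep &= ~_wedge_mask(params, frame, gx, gy, t0)
    d = _lc_offset(params, frame, gx, gy, rho)
    return float(d[keep].mean())


def with_seed(params: PhantomParams, seed: int) -> PhantomParams:
    """Convenience copy-with-new-seed."""
    return replace(params, seed=seed)
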
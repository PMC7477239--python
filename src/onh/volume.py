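"""Segmented optic-nerve-head volume container.

A :class:`SegmentedONHVolume` holds the delineated geometry of one eye at one
visit: the internal limiting membrane (ILM) height grid, the anterior lamina
cribrosa (LC) height grid (partial -- NaN marks nodes where the LC was not
delineated), and the ordered ring of Bruch's membrane opening (BMO) points.

Coordinate conventions
----------------------
* Lateral ``x`` runs along a B-scan (A-scan direction), ``y`` across B-scans.
* Grid node ``(i, j)`` sits at ``x = j * ascan_spacing``,
  ``y = i * bscan_spacing`` (node-registered, micrometres).
* Axial ``z`` is in micrometres with **larger z = more posterior** (deeper).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError

AXIAL_CONVENTION = "z-posterior"


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan metadata of an OCT volume.

    Defaults match a 73 B-scan x 384 A-scan radial-free raster with 62 um
    between B-scans covering a 15 x 15 degree field; the lateral A-scan
    spacing is not part of the instrument report and is exposed as an input
    (default 11.6 um makes the two field extents nearly equal).
    """

    n_bscans: int = 73
    n_ascans: int = 384
    bscan_spacing: float = 62.0
    ascan_spacing: float = 11.6
    axial_unit: float = 1.0  # um per stored axial unit; grids are stored in um

    def __post_init__(self) -> None:
        if self.n_bscans < 2 or self.n_ascans < 2:
            raise ParameterError("scan geometry needs at least 2 scans per axis")
        if min(self.bscan_spacing, self.ascan_spacing, self.axial_unit) <= 0:
            raise ParameterError("scan spacings must be positive")

    @property
    def field_extent(self) -> tuple[float, float]:
        """Physical (x, y) extent in micrometres."""
        return (
            (self.n_ascans - 1) * self.ascan_spacing,
            (self.n_bscans - 1) * self.bscan_spacing,
        )

    def x_coords(self) -> np.ndarray:
        return np.arange(self.n_ascans) * self.ascan_spacing

    def y_coords(self) -> np.ndarray:
        return np.arange(self.n_bscans) * self.bscan_spacing

    def node_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of node x, y positions, each shaped (n_bscans, n_ascans)."""
        return np.meshgrid(self.x_coords(), self.y_coords())


@dataclass(frozen=True)
class SegmentedONHVolume:
    """Delineated ONH geometry of one eye at one visit (all lengths in um)."""

    geometry: ScanGeometry
    ilm_height: np.ndarray
    lc_height: np.ndarray
    bmo_points: np.ndarray
    axial_range: tuple[float, float] = (-1500.0, 2000.0)
    axial_convention: str = AXIAL_CONVENTION
    name: str = "volume"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ilm_height", np.asarray(self.ilm_height, float))
        object.__setattr__(self, "lc_height", np.asarray(self.lc_height, float))
        object.__setattr__(self, "bmo_points", np.asarray(self.bmo_points, float))
        self.validate()

    def validate(self) -> None:
        g = self.geometry
        shape = (g.n_bscans, g.n_ascans)
        if self.ilm_height.shape != shape or self.lc_height.shape != shape:
            raise GeometryError(
                f"height grids must be shaped {shape}; got ILM "
                f"{self.ilm_height.shape}, LC {self.lc_height.shape}"
            )
        if self.bmo_points.ndim != 2 or self.bmo_points.shape[1] != 3:
            raise GeometryError("bmo_points must be an (n, 3) array")
        if len(self.bmo_points) < 8:
            raise GeometryError("the BMO ring needs at least 8 points")
        if not np.all(np.isfinite(self.bmo_points)):
            raise GeometryError("BMO points must be finite")
        if self.axial_convention != AXIAL_CONVENTION:
            raise GeometryError(
                f"unsupported axial convention {self.axial_convention!r}"
            )
        lo, hi = self.axial_range
        for label, grid in (("ILM", self.ilm_height), ("LC", self.lc_height)):
            finite = grid[np.isfinite(grid)]
            if finite.size and (finite.min() < lo or finite.max() > hi):
                raise GeometryError(
                    f"{label} heights fall outside the declared axial range "
                    f"[{lo}, {hi}] um"
                )

    def surface_points(self, which: str) -> np.ndarray:
        """Finite nodes of one surface as an (n, 3) array of um coordinates."""
        grid = {"ilm": self.ilm_height, "lc": self.lc_height}[which]
        xs, ys = self.geometry.node_grid()
        mask = np.isfinite(grid)
        return np.column_stack([xs[mask], ys[mask], grid[mask]])
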
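"""Regular latitude-longitude grid geometry and rasterization.

All grids are cell-edge registered: the grid's bounding box is split into
``nlat x nlon`` equal cells of ``resolution_deg`` degrees. Row 0 is the
northernmost row, column 0 the westernmost column; indexing is 0-based and
half-open in index space. Cell areas follow from the exact spherical-zone
formula, so a full-globe grid sums to 4*pi*R**2 at machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

EARTH_RADIUS_KM = 6371.0

#: Fine-to-coarse nesting factor: each coarse cell contains 6x6 fine cells
#: (0.5 degree coarse, 5 arc-minute fine).
FINE_PER_COARSE = 6


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular, cell-edge registered lat-lon grid.

    Parameters
    ----------
    resolution_deg : float
        Cell size in degrees (same for latitude and longitude).
    lat_min, lat_max, lon_min, lon_max : float
        Grid bounding box in degrees. Each extent must be a positive
        integer multiple of ``resolution_deg``.
    """

    resolution_deg: float
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max")
        if self.resolution_deg <= 0:
            raise ValueError("resolution must be positive")
        for span in (self.lat_max - self.lat_min, self.lon_max - self.lon_min):
            n = span / self.resolution_deg
            if abs(n - round(n)) > 1e-9 * max(1.0, n) or round(n) < 1:
                raise ValueError(
                    f"grid extent {span} is not a positive integer multiple of "
                    f"resolution {self.resolution_deg}"
                )

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution_deg))

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution_deg))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    def lat_edges(self) -> np.ndarray:
        """Latitude cell edges, descending from lat_max (row 0 is northernmost)."""
        return self.lat_max - self.resolution_deg * np.arange(self.nlat + 1)

    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.resolution_deg * np.arange(self.nlon + 1)

    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges()
        return 0.5 * (e[:-1] + e[1:])

    def lon_centers(self) -> np.ndarray:
        e = self.lon_edges()
        return 0.5 * (e[:-1] + e[1:])

    def refine(self, factor: int = FINE_PER_COARSE) -> "GridSpec":
        """The nested fine grid obtained by splitting each cell ``factor x factor``."""
        return GridSpec(
            self.resolution_deg / factor,
            self.lat_min, self.lat_max, self.lon_min, self.lon_max,
        )

    def nests_into(self, coarse: "GridSpec") -> bool:
        """True if this grid subdivides ``coarse`` exactly with integer factor."""
        if (self.lat_min, self.lat_max, self.lon_min, self.lon_max) != (
            coarse.lat_min, coarse.lat_max, coarse.lon_min, coarse.lon_max
        ):
            return False
        ratio = coarse.resolution_deg / self.resolution_deg
        return abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1


def cell_areas(grid: GridSpec, earth_radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Per-cell spherical areas in km**2, shape ``grid.shape``.

    Area of the cell bounded by latitudes [phi1, phi2] and a longitude span
    d_lambda (radians) is ``R**2 * d_lambda * (sin(phi2) - sin(phi1))``.
    Areas are constant along a latitude row and shrink toward the poles.
    """
    if grid.nlat < 1 or grid.nlon < 1:
        raise ValueError("degenerate grid with zero cells")
    edges = np.deg2rad(grid.lat_edges())
    dlon = np.deg2rad(grid.resolution_deg)
    # edges descend; take |sin(north) - sin(south)| per row
    band = np.sin(edges[:-1]) - np.sin(edges[1:])
    row_area = earth_radius_km**2 * dlon * band
    return np.repeat(row_area[:, None], grid.nlon, axis=1)


def upscale_fractions(fine: np.ndarray, fine_grid: GridSpec, coarse_grid: GridSpec) -> np.ndarray:
    """Aggregate a fine fraction field to the coarse grid, conserving area.

    Coarse value = (sum of fine_fraction * fine_area over the contained
    subcells) / coarse cell area, i.e. the coarse cell's covered-area
    fraction. Total class area is conserved exactly.
    """
    if not fine_grid.nests_into(coarse_grid):
        raise ValueError("fine grid does not nest into coarse grid")
    if fine.shape != fine_grid.shape:
        raise ValueError(f"field shape {fine.shape} != grid shape {fine_grid.shape}")
    k = int(round(coarse_grid.resolution_deg / fine_grid.resolution_deg))
    fa = cell_areas(fine_grid)
    ca = cell_areas(coarse_grid)
    weighted = (np.asarray(fine, dtype=float) * fa).reshape(
        coarse_grid.nlat, k, coarse_grid.nlon, k
    )
    total = weighted.sum(axis=(1, 3))
    out = total / ca
    # guard round-off just above 1
    return np.clip(out, 0.0, 1.0)


def _coverage_counts(polygon, fine_grid: GridSpec) -> np.ndarray:
    """Boolean mask of fine cells whose centre lies in/on the polygon."""
    geom = shapely.geometry.shape(polygon) if isinstance(polygon, dict) else polygon
    if geom.is_empty:
        return np.zeros(fine_grid.shape, dtype=bool)
    if not geom.is_valid:
        raise ValueError("invalid polygon geometry")
    lon_c = fine_grid.lon_centers()
    lat_c = fine_grid.lat_centers()
    xx, yy = np.meshgrid(lon_c, lat_c)
    # intersects includes the boundary: a centre on an edge counts as inside
    return shapely.intersects_xy(geom, xx.ravel(), yy.ravel()).reshape(fine_grid.shape)


def polygon_coverage(
    polygon,
    fine_grid: GridSpec,
    coarse_grid: GridSpec,
    *,
    area_weighted: bool = False,
) -> np.ndarray:
    """Fraction of each coarse cell covered by a polygon, via fine-cell centres.

    A fine cell is flagged iff its centre is inside the polygon (boundary
    counts as inside). The default coarse value is the count of flagged fine
    cells over the number of fine cells per coarse cell (36 for the 6x6
    nesting); ``area_weighted=True`` weights flagged subcells by their
    spherical area instead.

    ``polygon`` is a shapely (Multi)Polygon or a GeoJSON-style geometry dict.
    Antimeridian-crossing rings must be pre-split by the caller; coordinates
    are expected in the grid's longitude frame.
    """
    if not fine_grid.nests_into(coarse_grid):
        raise ValueError("fine grid does not nest into coarse grid")
    k = int(round(coarse_grid.resolution_deg / fine_grid.resolution_deg))
    flagged = _coverage_counts(polygon, fine_grid)
    blocks = flagged.reshape(coarse_grid.nlat, k, coarse_grid.nlon, k)
    if area_weighted:
        fa = cell_areas(fine_grid).reshape(coarse_grid.nlat, k, coarse_grid.nlon, k)
        return (blocks * fa).sum(axis=(1, 3)) / cell_areas(coarse_grid)
    return blocks.sum(axis=(1, 3)) / float(k * k)
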
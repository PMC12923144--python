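"""Regular lon/lat grids and rasters.

All rasters in the package live on a regular geographic grid (WGS84 lon/lat,
decimal degrees). Arrays are indexed ``[row, col]`` with row 0 at the southern
edge and latitude increasing with the row index; missing cells (land, or
outside the study region) are NaN. Spherical cell areas use the exact formula
for a lon/lat quadrilateral on a sphere of radius 6371 km,
``A = R^2 * dlon * (sin(lat_top) - sin(lat_bottom))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Grid:
    """A regular lon/lat grid defined by its lower-left corner and resolution.

    Parameters
    ----------
    lon_min, lat_min
        Coordinates of the outer lower-left corner (degrees).
    resolution
        Cell size in degrees (same for both axes).
    nlon, nlat
        Number of columns / rows.
    """

    lon_min: float
    lat_min: float
    resolution: float
    nlon: int
    nlat: int

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.nlon * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nlat * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.nlon) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.nlat) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) arrays of cell-centre coordinates, shape (nlat, nlon)."""
        return np.meshgrid(self.lon_centers(), self.lat_centers())

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points.

        Points outside the grid get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        bad = (col < 0) | (col >= self.nlon) | (row < 0) | (row >= self.nlat)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical area of every cell, shape (nlat, nlon), in km^2."""
        lat_edges = np.radians(
            self.lat_min + np.arange(self.nlat + 1) * self.resolution
        )
        band = (
            EARTH_RADIUS_KM**2
            * np.radians(self.resolution)
            * np.diff(np.sin(lat_edges))
        )
        return np.repeat(band[:, None], self.nlon, axis=1)

    def compatible(self, other: "Grid") -> bool:
        return (
            np.isclose(self.lon_min, other.lon_min)
            and np.isclose(self.lat_min, other.lat_min)
            and np.isclose(self.resolution, other.resolution)
            and self.shape == other.shape
        )


@dataclass
class Raster:
    """A single 2-D field on a :class:`Grid`; NaN marks missing cells."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return np.isfinite(self.values)

    def sample(self, lon, lat) -> np.ndarray:
        """Value of the cell containing each point (NaN off-grid)."""
        row, col = self.grid.index_of(lon, lat)
        out = np.full(np.shape(row), np.nan)
        ok = (row >= 0) & (col >= 0)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())


def mask_to_polygons(mask: np.ndarray, grid: Grid):
    """Dissolve the True cells of a boolean raster into a (multi)polygon.

    Cell footprints are exact grid squares, so the union has straight
    lon/lat edges and a lossless spherical area.
    """
    if not mask.any():
        return shapely.Polygon()
    res = grid.resolution
    # merge consecutive cells within each row into run rectangles before
    # unioning; far fewer geometries than one box per cell
    boxes = []
    for r in range(mask.shape[0]):
        row = mask[r]
        edges = np.diff(np.concatenate([[0], row.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for c0, c1 in zip(starts, ends):
            boxes.append(
                box(
                    grid.lon_min + c0 * res,
                    grid.lat_min + r * res,
                    grid.lon_min + c1 * res,
                    grid.lat_min + (r + 1) * res,
                )
            )
    return unary_union(boxes)


def rasterize(geometry, grid: Grid) -> np.ndarray:
    """Boolean mask of cells whose centre falls inside the geometry."""
    lon2d, lat2d = grid.center_mesh()
    if geometry is None or geometry.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    return shapely.contains_xy(geometry, lon2d, lat2d)


def spherical_area_km2(geometry) -> float:
    """Spherical area of a lon/lat polygon, exact for straight lon/lat edges.

    Uses the equal-area transform (lon_rad, sin(lat)): planar area in that
    space times R^2 equals the spherical area for edges that are straight in
    lon/lat (meridian and parallel segments exactly; short oblique segments to
    second order).
    """
    if geometry is None or geometry.is_empty:
        return 0.0
    transformed = shapely.transform(
        geometry,
        lambda coords: np.column_stack(
            [np.radians(coords[:, 0]), np.sin(np.radians(coords[:, 1]))]
        ),
    )
    return float(transformed.area) * EARTH_RADIUS_KM**2


def masked_area_km2(mask: np.ndarray, grid: Grid) -> float:
    """Total spherical area of the True cells of a raster mask."""
    return float(np.sum(grid.cell_areas_km2()[mask]))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a 6371-km sphere; broadcasts."""
    lon1, lat1, lon2, lat2 = map(np.radians, map(np.asarray, (lon1, lat1, lon2, lat2)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (text, row 0 = north)."""
    g = raster.grid
    vals = np.where(raster.mask, raster.values, nodata)
    header = (
        f"ncols {g.nlon}\nnrows {g.nlat}\n"
        f"xllcorner {g.lon_min}\nyllcorner {g.lat_min}\n"
        f"cellsize {g.resolution}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = Grid(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        resolution=header["cellsize"],
        nlon=int(header["ncols"]),
        nlat=int(header["nrows"]),
    )
    return Raster(grid, vals)
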
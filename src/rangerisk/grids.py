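"""Geographic grid geometry and plain-text raster I/O.

All rasters in this package live on regular latitude/longitude grids.  Rows
are stored north-to-south (row 0 is the northernmost band), columns
west-to-east, the usual raster convention.  Cell areas are geodesic on a
spherical Earth of radius 6371 km, so range areas and loss fractions are
area-weighted, never cell-counted.

Rasters are serialized as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by the
value matrix, one row per line, north first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Parameters
    ----------
    west, south
        Coordinates (decimal degrees) of the grid's lower-left corner.
    resolution_arcmin
        Cell size in arc-minutes (square cells).
    n_rows, n_cols
        Grid dimensions; row 0 is the northernmost row.
    """

    west: float
    south: float
    resolution_arcmin: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution_arcmin <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution_arcmin}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive extent (n_rows, n_cols >= 1)")
        if not (-180.0 <= self.west <= 180.0) or not (-90.0 <= self.south <= 90.0):
            raise ValueError("grid origin outside [-180,180] x [-90,90]")
        if self.south + self.n_rows * self.resolution_deg > 90.0 + 1e-9:
            raise ValueError("grid extends beyond the north pole")

    @property
    def resolution_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.resolution_deg

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.resolution_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.resolution_deg

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.resolution_deg

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        return (
            self.west + (col + 0.5) * self.resolution_deg,
            self.north - (row + 0.5) * self.resolution_deg,
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing a point; half-open [west,east) x [south,north)."""
        col = int(np.floor((lon - self.west) / self.resolution_deg))
        row_from_south = int(np.floor((lat - self.south) / self.resolution_deg))
        row = self.n_rows - 1 - row_from_south
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon},{lat}) outside grid extent")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        return (self.west <= lon < self.east) and (self.south <= lat < self.north)

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell areas broadcast to the full grid (km^2)."""
        row_areas = cell_area_km2(self.lat_centers(), self.resolution_arcmin)
        return np.repeat(row_areas[:, None], self.n_cols, axis=1)


def cell_area_km2(lat_center, resolution_arcmin: float):
    """Geodesic area of a grid cell on the 6371-km sphere.

    ``A = R^2 * dlambda * (sin(phi_n) - sin(phi_s))`` with the cell spanning
    ``resolution_arcmin`` in both axes, centered at ``lat_center``.  Latitude
    bounds are clipped to the poles, so polar cells get their true
    (triangle-like) area.
    """
    lat = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    half = resolution_arcmin / 60.0 / 2.0
    phi_n = np.radians(np.clip(lat + half, -90.0, 90.0))
    phi_s = np.radians(np.clip(lat - half, -90.0, 90.0))
    dlam = np.radians(resolution_arcmin / 60.0)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_n) - np.sin(phi_s))


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray,
                     mask: np.ndarray | None = None) -> None:
    """Write a raster layer as an ESRI ASCII grid. Masked cells become NODATA."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    out = values.copy()
    if mask is not None:
        out[mask] = _NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.resolution_deg!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    """Read an ESRI ASCII grid; returns (grid, values, mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.atleast_2d(values).reshape(n_rows, n_cols)
    grid = GridSpec(
        west=header["xllcorner"],
        south=header["yllcorner"],
        resolution_arcmin=header["cellsize"] * 60.0,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    nodata = header.get("nodata_value", _NODATA)
    mask = values == nodata
    return grid, values, mask
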
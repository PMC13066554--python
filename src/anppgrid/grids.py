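"""Grid geometry shared by every raster in a run.

All rasters are 2-D numpy arrays on a geographic (lon/lat) lattice with
cell-centre registration: the value at ``[i, j]`` refers to the centre of the
cell whose upper-left corner is ``(lon0 + j*cell, lat0 - i*cell)``.  NoData is
always NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr


@dataclass(frozen=True)
class GridMeta:
    """Geometry of a lon/lat raster grid.

    Parameters
    ----------
    rows, cols
        Grid shape.
    cell_size
        Cell edge length in degrees (> 0), identical in lon and lat.
    lon0, lat0
        Longitude/latitude of the grid's *upper-left corner* (GeoTIFF
        convention; cell centres sit half a cell inside).
    crs
        Coordinate reference tag; only geographic lon/lat is used.
    """

    rows: int
    cols: int
    cell_size: float
    lon0: float = 0.0
    lat0: float = 0.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")
        if not self.cell_size > 0:
            raise ValueError(f"cell size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        # north-to-south, matching row order of the array
        return self.lat0 - (np.arange(self.rows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each coordinate (no interpolation).

        Raises ``IndexError`` listing offending positions when a point falls
        outside the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.cell_size).astype(int)
        row = np.floor((self.lat0 - lat) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.cols) | (row < 0) | (row >= self.rows)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))
            raise IndexError(f"coordinates outside grid at positions {idx.tolist()}")
        return row, col

    def empty(self, fill: float = np.nan) -> np.ndarray:
        return np.full(self.shape, fill, dtype=float)


def annual_cube(values: np.ndarray, years, meta: GridMeta) -> xr.DataArray:
    """Wrap a ``(year, row, col)`` array as an annual climate/ANPP cube."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(years), meta.rows, meta.cols):
        raise ValueError(
            f"expected shape {(len(years), meta.rows, meta.cols)}, got {values.shape}"
        )
    return xr.DataArray(
        values,
        dims=("year", "lat", "lon"),
        coords={
            "year": np.asarray(list(years), dtype=int),
            "lat": meta.lat_centers(),
            "lon": meta.lon_centers(),
        },
        attrs={"cell_size": meta.cell_size, "crs": meta.crs},
    )


def monthly_cube(values: np.ndarray, years, meta: GridMeta) -> xr.DataArray:
    """Wrap a ``(year, month, row, col)`` array as a monthly cube."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(years), 12, meta.rows, meta.cols):
        raise ValueError(
            f"expected shape {(len(years), 12, meta.rows, meta.cols)}, got {values.shape}"
        )
    return xr.DataArray(
        values,
        dims=("year", "month", "lat", "lon"),
        coords={
            "year": np.asarray(list(years), dtype=int),
            "month": np.arange(1, 13),
            "lat": meta.lat_centers(),
            "lon": meta.lon_centers(),
        },
        attrs={"cell_size": meta.cell_size, "crs": meta.crs},
    )


def meta_of(cube: xr.DataArray) -> GridMeta:
    """Recover GridMeta from a cube's coordinates."""
    lat = np.asarray(cube["lat"].values)
    lon = np.asarray(cube["lon"].values)
    if lat.size > 1:
        cell = float(lat[0] - lat[1])
    elif lon.size > 1:
        cell = float(lon[1] - lon[0])
    else:
        cell = float(cube.attrs.get("cell_size", 1.0))
    return GridMeta(
        rows=lat.size,
        cols=lon.size,
        cell_size=cell,
        lon0=float(lon[0] - cell / 2),
        lat0=float(lat[0] + cell / 2),
        crs=str(cube.attrs.get("crs", "EPSG:4326")),
    )
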
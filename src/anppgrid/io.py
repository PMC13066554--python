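"""Raster I/O and product-file naming.

Rasters are written as single-band float32 GeoTIFFs with NaN NoData and
cell-centre registration.  Georeferencing is carried by the standard GeoTIFF
``ModelPixelScale``/``ModelTiepoint`` tags; the full :class:`GridMeta` is also
embedded as JSON in the image description so a read is a lossless round-trip.

Product files follow the dataset naming grammar::

    map_YYYY.tif                    historical annual map
    map_MODEL_SSP_YYYY.tif          one scenario member, one year
    map_STATISTIC_SSP_YYYY.tif      ensemble statistic layer

with STATISTIC one of mean, std, median, p05, p95 and SSP one of
SSP245, SSP585.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .grids import GridMeta

STATISTICS = ("mean", "std", "median", "p05", "p95")
SCENARIOS = ("SSP245", "SSP585")

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_raster(path, raster: np.ndarray, meta: GridMeta) -> Path:
    """Write a 2-D raster as a GeoTIFF; NaN is the NoData sentinel."""
    path = Path(path)
    raster = np.asarray(raster, dtype=np.float32)
    if raster.shape != meta.shape:
        raise ValueError(f"raster shape {raster.shape} does not match grid {meta.shape}")
    finite = raster[np.isfinite(raster)]
    if finite.size and not np.all(np.isfinite(finite)):  # pragma: no cover
        raise ValueError("raster contains non-finite, non-NaN values")
    desc = json.dumps(
        {
            "rows": meta.rows,
            "cols": meta.cols,
            "cell_size": meta.cell_size,
            "lon0": meta.lon0,
            "lat0": meta.lat0,
            "crs": meta.crs,
            "nodata": "NaN",
            "units": "g m-2",
        },
        sort_keys=True,
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (meta.cell_size, meta.cell_size, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, meta.lon0, meta.lat0, 0.0), True),
    ]
    tifffile.imwrite(path, raster, description=desc, extratags=extratags, software=None)
    return path


def read_raster(path, expect_meta: GridMeta | None = None) -> tuple[np.ndarray, GridMeta]:
    """Read a raster and its grid metadata; optionally enforce a run's grid."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        raster = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            d = json.loads(desc.value)
            meta = GridMeta(
                rows=int(d["rows"]),
                cols=int(d["cols"]),
                cell_size=float(d["cell_size"]),
                lon0=float(d["lon0"]),
                lat0=float(d["lat0"]),
                crs=str(d.get("crs", "EPSG:4326")),
            )
        else:  # fall back to the GeoTIFF tags
            scale = page.tags[_MODEL_PIXEL_SCALE].value
            tie = page.tags[_MODEL_TIEPOINT].value
            meta = GridMeta(
                rows=raster.shape[0],
                cols=raster.shape[1],
                cell_size=float(scale[0]),
                lon0=float(tie[3]),
                lat0=float(tie[4]),
            )
    if expect_meta is not None and meta != expect_meta:
        raise ValueError(
            f"grid mismatch: file {path.name} has cell size {meta.cell_size} and shape "
            f"{meta.shape}, run expects cell size {expect_meta.cell_size} and shape "
            f"{expect_meta.shape}"
        )
    return raster, meta


@dataclass(frozen=True)
class ProductName:
    """Parsed identity of one product file."""

    era: str  # "historical" | "future"
    year: int
    model: str | None = None
    scenario: str | None = None
    statistic: str | None = None

    def __post_init__(self) -> None:
        if self.era not in ("historical", "future"):
            raise ValueError(f"unknown era {self.era!r}")
        if self.era == "historical":
            if self.model or self.scenario or self.statistic:
                raise ValueError("historical products carry only a year")
        else:
            if self.scenario not in SCENARIOS:
                raise ValueError(f"future products need a scenario in {SCENARIOS}")
            if (self.model is None) == (self.statistic is None):
                raise ValueError("future products carry either a model or a statistic")
            if self.statistic is not None and self.statistic not in STATISTICS:
                raise ValueError(f"statistic must be one of {STATISTICS}")
            if self.model is not None and ("_" in self.model or not self.model):
                raise ValueError("model id must be non-empty and free of underscores")


def format_name(p: ProductName) -> str:
    if p.era == "historical":
        return f"map_{p.year}.tif"
    tag = p.model if p.model is not None else p.statistic
    return f"map_{tag}_{p.scenario}_{p.year}.tif"


_HIST_RE = re.compile(r"^map_(\d{4})\.tif$")
_FUT_RE = re.compile(r"^map_([^_]+(?:-[^_]+)*)_(SSP\d{3})_(\d{4})\.tif$")


def parse_name(name: str) -> ProductName:
    m = _HIST_RE.match(name)
    if m:
        return ProductName(era="historical", year=int(m.group(1)))
    m = _FUT_RE.match(name)
    if m:
        tag, ssp, year = m.group(1), m.group(2), int(m.group(3))
        if ssp not in SCENARIOS:
            raise ValueError(f"unrecognised scenario in filename {name!r}")
        if tag in STATISTICS:
            return ProductName(era="future", year=year, scenario=ssp, statistic=tag)
        return ProductName(era="future", year=year, scenario=ssp, model=tag)
    raise ValueError(f"unrecognised product filename {name!r}")
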
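"""Predictor construction: annual aggregation, climate normals, anomalies,
and the per-observation feature table.

Anomalies follow the two standard definitions: for precipitation, radiation,
potential evapotranspiration and the aridity index the anomaly is *relative*,

    a = (x_act - x_mean) / x_mean,

while for temperature — whose multi-year mean can sit near 0 degC, where a
ratio would explode — it is the plain *difference* in degC,

    a = x_act - x_mean,

with x_mean the per-cell mean over the baseline window (default 1970-2000).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridMeta, annual_cube, meta_of

logger = logging.getLogger(__name__)

#: variables whose anomaly is a relative change (Eq.-style ratio)
RELATIVE_KINDS = frozenset({"precipitation", "radiation", "pet", "aridity"})
ABSOLUTE_KINDS = frozenset({"temperature"})
#: |x_mean| below this (variable units) makes a relative anomaly undefined
MEAN_EPSILON = 1e-6

SUMMED = frozenset({"precipitation", "pet"})
AVERAGED = frozenset({"temperature", "radiation"})

STATIC_PREDICTORS = (
    "soil_ph",
    "total_n",
    "soc",
    "cn_ratio",
    "clay_pct",
    "silt_pct",
    "bulk_density",
    "elevation",
    "slope",
    "aspect",
)


def aggregate_annual(monthly: xr.DataArray, kind: str) -> xr.DataArray:
    """Collapse a monthly cube to annual values.

    Precipitation and PET are summed over months; temperature and radiation
    averaged.  The aridity index must not be aggregated from monthly ratios:
    use :func:`annual_aridity` on the summed series instead.
    """
    if kind == "aridity":
        raise ValueError(
            "aggregate the aridity index via annual_aridity(precipitation, pet), "
            "not by averaging monthly ratios"
        )
    if "month" not in monthly.dims:
        raise ValueError("expected a monthly cube with a 'month' dimension")
    if monthly.sizes["month"] != 12:
        missing = sorted(set(range(1, 13)) - set(np.atleast_1d(monthly["month"].values)))
        raise ValueError(f"incomplete years: missing months {missing}")
    if kind in SUMMED:
        return monthly.sum("month")
    if kind in AVERAGED:
        return monthly.mean("month")
    raise ValueError(f"unknown variable kind {kind!r}")


def annual_aridity(precip_annual: xr.DataArray, pet_annual: xr.DataArray) -> xr.DataArray:
    """Aridity index = annual precipitation / annual PET (NaN where PET <= 0)."""
    pet = pet_annual.where(pet_annual > 0)
    return precip_annual / pet


def compute_normals(annual: xr.DataArray, window: tuple[int, int]) -> np.ndarray:
    """Cellwise mean over the baseline window (inclusive); NaN propagates."""
    start, end = window
    if start > end:
        raise ValueError(f"empty baseline window {start}-{end}")
    years = np.asarray(annual["year"].values)
    sel = (years >= start) & (years <= end)
    if not sel.any():
        raise ValueError(f"window {start}-{end} has no overlap with years {years.min()}-{years.max()}")
    return annual.values[sel].mean(axis=0)


def compute_anomaly(kind: str, x_act, x_mean, eps: float = MEAN_EPSILON):
    """Anomaly of actual value(s) against the baseline mean.

    Relative kinds with |x_mean| <= eps yield NaN (flagged undefined rather
    than an extreme outlier).  Works elementwise on arrays.
    """
    x_act = np.asarray(x_act, dtype=float)
    x_mean = np.asarray(x_mean, dtype=float)
    if kind in ABSOLUTE_KINDS:
        return x_act - x_mean
    if kind in RELATIVE_KINDS:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (x_act - x_mean) / x_mean
        out = np.where(np.abs(x_mean) <= eps, np.nan, out)
        return out
    raise ValueError(f"unknown variable kind {kind!r}")


def anomaly_cube(annual: xr.DataArray, normal: np.ndarray, kind: str) -> xr.DataArray:
    """Per-year anomaly cube against a fixed normal field."""
    vals = compute_anomaly(kind, annual.values, normal[None])
    return annual_cube(vals, annual["year"].values, meta_of(annual))


BASE_PREDICTORS = (
    "mean_anpp",
    "baseline_aridity",
    "baseline_pet",
    "baseline_precipitation",
    "baseline_radiation",
    "baseline_temperature",
    "anomaly_aridity",
    "anomaly_pet",
    "anomaly_precipitation",
    "anomaly_radiation",
    "anomaly_temperature",
)


def build_feature_table(
    sites: pd.DataFrame,
    normals: Mapping[str, np.ndarray],
    annual_cubes: Mapping[str, xr.DataArray],
    mean_anpp: np.ndarray,
    meta: GridMeta,
    static_rasters: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Join each observation with its cell's predictors.

    Output columns: response ``anpp_g_m2`` first, then the 11 base predictors
    (mean ANPP, five baselines, five sampling-year anomalies, alphabetical
    within group), then any statics, then provenance (site_id, year, lon,
    lat).  Rows with any undefined predictor are dropped with a logged count.
    """
    required = {"site_id", "lon", "lat", "year", "anpp_g_m2"}
    if not required.issubset(sites.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    try:
        row, col = meta.cell_of(sites["lon"].values, sites["lat"].values)
    except IndexError:
        ok = []
        for sid, lon, lat in zip(sites["site_id"], sites["lon"], sites["lat"]):
            try:
                meta.cell_of(lon, lat)
            except IndexError:
                ok.append(sid)
        raise IndexError(f"sites outside grid: {ok}")

    out = pd.DataFrame({"anpp_g_m2": sites["anpp_g_m2"].values})
    out["mean_anpp"] = np.asarray(mean_anpp, dtype=float)[row, col]

    variables = sorted(normals)
    for name in variables:
        out[f"baseline_{name}"] = np.asarray(normals[name], dtype=float)[row, col]
    for name in variables:
        cube = annual_cubes[name]
        cube_years = np.asarray(cube["year"].values)
        yi = np.searchsorted(cube_years, sites["year"].values)
        yi_clipped = np.clip(yi, 0, len(cube_years) - 1)
        valid_year = cube_years[yi_clipped] == sites["year"].values
        act = cube.values[yi_clipped, row, col]
        act = np.where(valid_year, act, np.nan)
        out[f"anomaly_{name}"] = compute_anomaly(name, act, out[f"baseline_{name}"].values)

    if static_rasters is not None:
        for name in sorted(static_rasters):
            out[name] = np.asarray(static_rasters[name], dtype=float)[row, col]

    for c in ("site_id", "year", "lon", "lat"):
        out[c] = sites[c].values

    predictors = [c for c in out.columns if c not in required]
    keep = ~out[["anpp_g_m2", *predictors]].isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with undefined predictors", dropped)
    return out[keep].reset_index(drop=True)


def predictor_columns(table: pd.DataFrame) -> list[str]:
    """The modelling view's predictor columns, in stable order."""
    base = [c for c in BASE_PREDICTORS if c in table.columns]
    statics = [c for c in STATIC_PREDICTORS if c in table.columns]
    return base + statics
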
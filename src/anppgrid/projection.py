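"""Scenario preprocessing and gridded prediction.

Quantile delta mapping (QDM) aligns a climate model's distribution with the
observed calibration-window distribution while preserving the model's own
quantile changes between its historical and target windows: for a target
value x with quantile tau in the target window,

    additive       x' = F_obs^-1(tau) + [x - F_hist^-1(tau)]
    multiplicative x' = F_obs^-1(tau) * x / F_hist^-1(tau)

with empirical, linearly interpolated quantile functions.  Additive mode
serves temperature; multiplicative mode the non-negative variables.  The
correction is applied per calendar month, per cell; the aridity index is
recomputed from corrected precipitation and PET so the ratio identity stays
intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.stats import rankdata

from . import features as feat
from .grids import GridMeta, meta_of, monthly_cube
from .harness import FittedModel

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class QdmSpec:
    """Correction settings for one variable."""

    kind: str
    mode: str | None = None  # "additive" | "multiplicative"; default by kind
    calibration: tuple[int, int] = (1970, 2000)
    n_quantiles: int | None = None  # default min(n, 100)

    def __post_init__(self) -> None:
        if self.mode is not None and self.mode not in ("additive", "multiplicative"):
            raise ValueError("mode must be 'additive' or 'multiplicative'")
        if self.n_quantiles is not None and self.n_quantiles < 2:
            raise ValueError("need at least 2 quantiles")
        if self.calibration[0] > self.calibration[1]:
            raise ValueError("empty calibration window")

    @property
    def effective_mode(self) -> str:
        if self.mode is not None:
            return self.mode
        return "additive" if self.kind in feat.ABSOLUTE_KINDS else "multiplicative"


def _qf(series: np.ndarray, tau: np.ndarray, n_quantiles: int | None) -> np.ndarray:
    """Empirical quantile function with linear interpolation."""
    s = np.sort(series)
    m = min(len(s), 100) if n_quantiles is None else min(len(s), n_quantiles)
    taus = np.linspace(0.0, 1.0, m)
    knots = np.quantile(s, taus) if m < len(s) else s
    return np.interp(tau, taus, knots)


def qdm_correct(
    obs_ref: np.ndarray,
    model_hist: np.ndarray,
    model_target: np.ndarray,
    spec: QdmSpec,
) -> np.ndarray:
    """Correct a 1-D target series against observed/hist reference samples."""
    obs_ref = np.asarray(obs_ref, dtype=float)
    model_hist = np.asarray(model_hist, dtype=float)
    x = np.asarray(model_target, dtype=float)
    mode = spec.effective_mode
    if mode == "multiplicative" and (np.any(obs_ref < 0) or np.any(x < 0)):
        raise ValueError("multiplicative mode requires non-negative series")
    nt = len(x)
    st = np.sort(x)
    tau = np.interp(x, st, np.linspace(0.0, 1.0, nt))
    obs_q = _qf(obs_ref, tau, spec.n_quantiles)
    hist_q = _qf(model_hist, tau, spec.n_quantiles)
    if mode == "additive":
        return obs_q + (x - hist_q)
    small = np.abs(hist_q) < _EPS
    if small.any():
        logger.warning("flooring %d near-zero historical quantiles at %g", int(small.sum()), _EPS)
        hist_q = np.where(small, _EPS, hist_q)
    return obs_q * x / hist_q


def _colwise_tau(values: np.ndarray) -> np.ndarray:
    """Empirical CDF position of each value within its own column."""
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 values per series")
    ranks = rankdata(values, axis=0, method="average")
    return (ranks - 1.0) / (n - 1.0)


def _colwise_quantile(sorted_vals: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Linear-interpolation quantile lookup per column.

    ``sorted_vals``: (n, cells) ascending per column; ``tau``: (k, cells)."""
    n = sorted_vals.shape[0]
    pos = np.clip(tau, 0.0, 1.0) * (n - 1)
    lo = np.minimum(pos.astype(int), n - 2)
    w = pos - lo
    a = np.take_along_axis(sorted_vals, lo, axis=0)
    b = np.take_along_axis(sorted_vals, lo + 1, axis=0)
    return a * (1.0 - w) + b * w


def qdm_correct_cube(
    obs_monthly: xr.DataArray,
    model_monthly: xr.DataArray,
    spec: QdmSpec,
    target_years: tuple[int, int] | None = None,
) -> xr.DataArray:
    """Apply QDM per calendar month and per cell to a monthly model cube.

    ``obs_monthly`` supplies the observed calibration distribution; the model
    cube's calibration-window years form the historical distribution and the
    (default: all) ``target_years`` are corrected.
    """
    mode = spec.effective_mode
    cal0, cal1 = spec.calibration
    oy = np.asarray(obs_monthly["year"].values)
    my = np.asarray(model_monthly["year"].values)
    o_sel = (oy >= cal0) & (oy <= cal1)
    h_sel = (my >= cal0) & (my <= cal1)
    if not o_sel.any() or not h_sel.any():
        raise ValueError(f"calibration window {cal0}-{cal1} empty in observed or modelled series")
    if target_years is None:
        t_sel = np.ones(my.size, dtype=bool)
    else:
        t_sel = (my >= target_years[0]) & (my <= target_years[1])

    rows, cols = obs_monthly.shape[-2:]
    ncell = rows * cols
    out = model_monthly.values.copy()
    for m in range(12):
        obs = obs_monthly.values[o_sel, m].reshape(-1, ncell)
        hist = model_monthly.values[h_sel, m].reshape(-1, ncell)
        targ = model_monthly.values[t_sel, m].reshape(-1, ncell)
        tau = _colwise_tau(targ)
        obs_q = _colwise_quantile(np.sort(obs, axis=0), tau)
        hist_q = _colwise_quantile(np.sort(hist, axis=0), tau)
        if mode == "additive":
            corr = obs_q + (targ - hist_q)
        else:
            hist_q = np.where(np.abs(hist_q) < _EPS, _EPS, hist_q)
            corr = obs_q * targ / hist_q
        out[t_sel, m] = corr.reshape(-1, rows, cols)
    return monthly_cube(out, my, meta_of(model_monthly))


def bilinear_regrid(raster: np.ndarray, src: GridMeta, dst: GridMeta) -> np.ndarray:
    """Bilinear resampling between cell-centre registered lon/lat grids.

    Exact for affine fields; NaN-aware (any NaN corner yields NaN); target
    points outside the source centre lattice clamp to the edge cells.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.shape != src.shape:
        raise ValueError("raster shape does not match source grid")
    lon_t = dst.lon_centers()
    lat_t = dst.lat_centers()
    if lon_t[-1] < src.lon0 or lon_t[0] > src.lon0 + src.cols * src.cell_size:
        raise ValueError("target grid does not overlap the source extent")
    # fractional position in source cell-centre coordinates
    x = (lon_t - (src.lon0 + 0.5 * src.cell_size)) / src.cell_size
    y = ((src.lat0 - 0.5 * src.cell_size) - lat_t) / src.cell_size
    x = np.clip(x, 0.0, src.cols - 1.0)
    y = np.clip(y, 0.0, src.rows - 1.0)
    j0 = np.minimum(x.astype(int), src.cols - 2) if src.cols > 1 else np.zeros_like(x, int)
    i0 = np.minimum(y.astype(int), src.rows - 2) if src.rows > 1 else np.zeros_like(y, int)
    wx = (x - j0)[None, :]
    wy = (y - i0)[:, None]
    i0 = i0[:, None]
    j0 = j0[None, :]
    q00 = raster[i0, j0]
    q01 = raster[i0, j0 + 1] if src.cols > 1 else q00
    q10 = raster[i0 + 1, j0] if src.rows > 1 else q00
    q11 = raster[i0 + 1, j0 + 1] if src.rows > 1 and src.cols > 1 else q00
    return (
        q00 * (1 - wy) * (1 - wx)
        + q01 * (1 - wy) * wx
        + q10 * wy * (1 - wx)
        + q11 * wy * wx
    )


def predict_map(
    model: FittedModel,
    normals: dict[str, np.ndarray],
    annual_values: dict[str, np.ndarray],
    mean_anpp: np.ndarray,
    mask: np.ndarray,
    static_rasters: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Predict one year's ANPP raster from per-cell features.

    Cells off the mask or with any undefined predictor come out NaN; the
    prediction is floored at 0 g m-2.
    """
    layers: dict[str, np.ndarray] = {"mean_anpp": np.asarray(mean_anpp, dtype=float)}
    for name, normal in normals.items():
        layers[f"baseline_{name}"] = np.asarray(normal, dtype=float)
        layers[f"anomaly_{name}"] = feat.compute_anomaly(
            name, np.asarray(annual_values[name], dtype=float), normal
        )
    if static_rasters:
        layers.update({k: np.asarray(v, dtype=float) for k, v in static_rasters.items()})
    missing = [n for n in model.feature_names if n not in layers]
    if missing:
        raise ValueError(f"schema mismatch: no raster layer for predictors {missing}")
    stack = np.stack([layers[n] for n in model.feature_names], axis=-1)
    shape = stack.shape[:2]
    flat = stack.reshape(-1, stack.shape[-1])
    ok = np.asarray(mask, dtype=bool).ravel() & np.isfinite(flat).all(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if ok.any():
        out[ok] = np.maximum(model.predict(flat[ok]), 0.0)
    return out.reshape(shape)


def ensemble_layers(members: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Cellwise ensemble statistics over >= 2 member rasters.

    Returns mean, population std, median, and 5th/95th percentiles (linear
    interpolation); a cell is NaN in every layer if any member is NaN there.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 ensemble members")
    shape = np.asarray(members[0]).shape
    for m in members[1:]:
        if np.asarray(m).shape != shape:
            raise ValueError("ensemble members must share a grid")
    stack = np.stack([np.asarray(m, dtype=float) for m in members])
    bad = ~np.isfinite(stack).all(axis=0)
    with np.errstate(invalid="ignore"):
        layers = {
            "mean": stack.mean(axis=0),
            "std": stack.std(axis=0, ddof=0),
            "median": np.median(stack, axis=0),
            "p05": np.percentile(stack, 5, axis=0),
            "p95": np.percentile(stack, 95, axis=0),
        }
    for v in layers.values():
        v[bad] = np.nan
    return layers
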
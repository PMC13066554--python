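"""Temporal reliability battery.

Residual diagnostics check for year-specific bias: residuals
(observed - predicted) are binned into five-year intervals anchored at the
earliest sampling year, each bin summarised by its *relative residual
standard deviation* — SD of residuals divided by mean observed ANPP — and the
relationship of that statistic to bin sample size is quantified by OLS.

Gridwise correlation checks interannual dynamics: the per-cell Pearson r
between the predicted ANPP series and an independent reference NPP series,
summarised as the fraction of valid cells with r > 0 (the reference is a
stand-in for satellite or vegetation-model NPP products, usable because the
ANPP/NPP ratio of a given cell is taken as temporally stable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidualDiagnostics:
    residuals: pd.DataFrame  # year, observed, predicted, residual
    bins: pd.DataFrame  # bin_start, bin_end, n, rel_resid_sd
    slope: float  # OLS of rel_resid_sd on n
    intercept: float
    r2: float
    p_value: float


def residual_diagnostics(
    obs, pred, years, bin_width: int = 5
) -> ResidualDiagnostics:
    """Five-year-bin residual diagnostics with an OLS fit on sample size."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    years = np.asarray(years, dtype=int)
    if not (len(obs) == len(pred) == len(years)):
        raise ValueError("obs, pred and years must have equal length")
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    resid = obs - pred
    table = pd.DataFrame({"year": years, "observed": obs, "predicted": pred, "residual": resid})

    start = int(years.min())
    bin_id = (years - start) // bin_width
    rows = []
    for b in np.unique(bin_id):
        sel = bin_id == b
        n = int(sel.sum())
        if n < 2:
            logger.info("excluding %d-year bin starting %d with n=%d", bin_width, start + b * bin_width, n)
            continue
        mean_obs = obs[sel].mean()
        sd = float(np.std(resid[sel], ddof=1))
        rel = sd / mean_obs if mean_obs != 0 else np.nan
        if mean_obs == 0:
            logger.warning("bin starting %d has zero mean observed ANPP", start + b * bin_width)
        rows.append(
            {
                "bin_start": int(start + b * bin_width),
                "bin_end": int(start + (b + 1) * bin_width - 1),
                "n": n,
                "rel_resid_sd": rel,
            }
        )
    bins = pd.DataFrame(rows)
    fit_ok = bins["rel_resid_sd"].notna() if len(bins) else pd.Series(dtype=bool)
    if len(bins) >= 3 and fit_ok.sum() >= 3 and bins.loc[fit_ok, "n"].nunique() > 1:
        lr = stats.linregress(bins.loc[fit_ok, "n"], bins.loc[fit_ok, "rel_resid_sd"])
        slope, intercept = float(lr.slope), float(lr.intercept)
        r2, p = float(lr.rvalue**2), float(lr.pvalue)
    else:
        slope = intercept = r2 = p = np.nan
    return ResidualDiagnostics(
        residuals=table, bins=bins, slope=slope, intercept=intercept, r2=r2, p_value=p
    )


@dataclass(frozen=True)
class TemporalConcordance:
    r_map: np.ndarray  # per-cell Pearson r, NaN where undefined
    fraction_positive: float
    n_valid: int


def gridwise_correlation(anpp: xr.DataArray, reference: xr.DataArray) -> TemporalConcordance:
    """Per-cell Pearson r between two annual cubes over their common years."""
    ya = np.asarray(anpp["year"].values)
    yb = np.asarray(reference["year"].values)
    common = np.intersect1d(ya, yb)
    if common.size < 3:
        raise ValueError(f"only {common.size} overlapping years; need at least 3")
    a = anpp.sel(year=common).values
    b = reference.sel(year=common).values
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("cubes must share a grid")
    ok = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    sa = np.sqrt((az**2).sum(axis=0))
    sb = np.sqrt((bz**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az * bz).sum(axis=0) / (sa * sb)
    r = np.where(ok & (sa > 0) & (sb > 0), r, np.nan)
    valid = np.isfinite(r)
    n_valid = int(valid.sum())
    frac = float((r[valid] > 0).mean()) if n_valid else np.nan
    return TemporalConcordance(r_map=r, fraction_positive=frac, n_valid=n_valid)


def fraction_positive_summary(
    anpp: xr.DataArray, members: dict[str, xr.DataArray]
) -> pd.DataFrame:
    """Fraction-positive per reference member plus the ensemble mean.

    Mirrors multi-model reporting: one row per member and a final
    ``ensemble_mean`` row computed against the mean of all member cubes.
    """
    if not members:
        raise ValueError("no reference members given")
    rows = []
    for name, cube in members.items():
        tc = gridwise_correlation(anpp, cube)
        rows.append({"member": name, "fraction_positive": tc.fraction_positive, "n_valid": tc.n_valid})
    common = None
    for cube in members.values():
        yrs = np.asarray(cube["year"].values)
        common = yrs if common is None else np.intersect1d(common, yrs)
    stacked = [cube.sel(year=common) for cube in members.values()]
    mean_cube = stacked[0].copy(data=np.mean([c.values for c in stacked], axis=0))
    tc = gridwise_correlation(anpp, mean_cube)
    rows.append(
        {"member": "ensemble_mean", "fraction_positive": tc.fraction_positive, "n_valid": tc.n_valid}
    )
    return pd.DataFrame(rows)
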
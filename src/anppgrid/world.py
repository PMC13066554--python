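"""Self-contained synthetic study system for the upscaling pipeline.

The generator produces everything the real analysis would read from archives:
spatially autocorrelated climate baselines for five variables (temperature,
precipitation, radiation, potential evapotranspiration, and the aridity index
P/PET), trended and noisy annual climate histories expanded to monthly cubes,
a known ground-truth ANPP response with interannual climate sensitivity, the
multi-year-mean ANPP raster, a grassland mask, sparse noisy site observations,
reference NPP series, and biased "climate model" runs for bias-correction
exercises.

Ground-truth response
---------------------
Annual truth at a cell is

    ANPP(c, y) = B(c) * max(1 + sum_v s_v * a_v(c, y), floor) + eps

where ``B`` is a smooth positive baseline productivity surface (saturating in
baseline precipitation, gently increasing with baseline temperature), ``a_v``
are the per-year climate anomalies of the generated annual climate (relative
for precipitation/radiation/PET/aridity, absolute in deg C for temperature),
``s_v`` is the known sensitivity vector and ``eps`` optional process noise.
Because truth is, by construction, baseline productivity modulated only by
climate anomalies, anomaly-feature recovery by the downstream model is a
well-posed test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import features as feat
from .grids import GridMeta, annual_cube, monthly_cube

logger = logging.getLogger(__name__)

VARIABLES = ("temperature", "precipitation", "radiation", "pet", "aridity")
#: variables generated directly; aridity is derived as precipitation / PET
GENERATED = ("temperature", "precipitation", "radiation", "pet")

# Fixed monthly weights: a mild northern-hemisphere seasonal cycle.  Summed
# variables (precipitation, PET) distribute the annual total by _SUM_WEIGHTS;
# averaged variables (temperature, radiation) oscillate around the annual
# value with zero-mean offsets scaled by the variable's seasonal amplitude.
_SUM_WEIGHTS = np.array(
    [0.04, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.13, 0.10, 0.08, 0.06, 0.05]
)
_SEASON_OFFSET = np.cos((np.arange(12) - 6.5) / 12 * 2 * np.pi)
_SEASON_OFFSET = _SEASON_OFFSET - _SEASON_OFFSET.mean()


@dataclass(frozen=True)
class VariableSpec:
    """Generating parameters for one climate variable."""

    mean: float  # spatial mean of the baseline field
    spatial_sd: float  # SD of the smoothed spatial variation
    length_scale: float  # Gaussian-filter sigma, in cells
    noise_sd: float  # interannual (year-to-year) SD, additive
    trend: float  # linear trend per year, centred on the baseline window
    floor: float | None = None  # clip for non-negative variables
    seasonal_amplitude: float = 0.0  # for averaged variables
    monthly_jitter_sd: float = 0.0


@dataclass(frozen=True)
class WorldSpec:
    """Full parameterisation of a synthetic world."""

    rows: int = 40
    cols: int = 40
    cell_size: float = 0.5
    lon0: float = 0.0
    lat0: float = 50.0
    year_start: int = 1958
    year_end: int = 2023
    baseline_start: int = 1970
    baseline_end: int = 2000
    variables: dict[str, VariableSpec] = field(default_factory=lambda: dict(_DEFAULT_VARIABLES))
    # true-response parameters
    anpp_max: float = 600.0  # asymptotic baseline productivity, g m-2
    precip_half_saturation: float = 350.0  # mm at which B reaches anpp_max/2... scaled
    temperature_gain: float = 0.012  # per deg C multiplier exponent on B
    temperature_ref: float = 8.0  # deg C
    sensitivity: dict[str, float] = field(
        default_factory=lambda: {
            "temperature": 0.03,  # per deg C
            "precipitation": 0.55,  # per unit relative anomaly
            "radiation": 0.10,
            "pet": -0.20,
            "aridity": 0.0,
        }
    )
    response_floor: float = 0.05  # lower clip on the anomaly multiplier
    process_noise_sd: float = 0.0  # g m-2, on annual truth
    mask_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not (self.year_start <= self.baseline_start <= self.baseline_end <= self.year_end):
            raise ValueError(
                f"baseline window {self.baseline_start}-{self.baseline_end} must lie "
                f"within the year range {self.year_start}-{self.year_end}"
            )
        for name, v in self.variables.items():
            if v.noise_sd < 0 or v.spatial_sd < 0 or v.monthly_jitter_sd < 0:
                raise ValueError(f"negative SD in variable spec {name!r}")
        if self.process_noise_sd < 0:
            raise ValueError("process noise SD must be >= 0")
        if not (0 < self.mask_fraction <= 1):
            raise ValueError("mask fraction must be in (0, 1]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def baseline_window(self) -> tuple[int, int]:
        return (self.baseline_start, self.baseline_end)

    @property
    def meta(self) -> GridMeta:
        return GridMeta(self.rows, self.cols, self.cell_size, self.lon0, self.lat0)


_DEFAULT_VARIABLES: dict[str, VariableSpec] = {
    "temperature": VariableSpec(
        mean=8.0, spatial_sd=5.0, length_scale=6.0, noise_sd=0.7, trend=0.02,
        seasonal_amplitude=10.0, monthly_jitter_sd=0.3,
    ),
    "precipitation": VariableSpec(
        mean=550.0, spatial_sd=200.0, length_scale=6.0, noise_sd=110.0, trend=0.3,
        floor=5.0, monthly_jitter_sd=1.0,
    ),
    "radiation": VariableSpec(
        mean=180.0, spatial_sd=25.0, length_scale=6.0, noise_sd=8.0, trend=0.0,
        floor=5.0, monthly_jitter_sd=0.5,
    ),
    "pet": VariableSpec(
        mean=900.0, spatial_sd=220.0, length_scale=6.0, noise_sd=60.0, trend=0.8,
        floor=50.0, monthly_jitter_sd=1.0,
    ),
}


@dataclass
class SyntheticWorld:
    """A generated study system with its full ground truth."""

    spec: WorldSpec
    monthly: dict[str, xr.DataArray]  # per variable, dims (year, month, lat, lon)
    annual_truth: dict[str, xr.DataArray]  # generating annual climate
    true_anomalies: dict[str, xr.DataArray]  # anomalies used by the response
    baseline_fields: dict[str, np.ndarray]
    anpp: xr.DataArray  # true annual ANPP, dims (year, lat, lon)
    mean_anpp: np.ndarray  # baseline-window mean of truth
    mask: np.ndarray  # boolean grassland mask

    @property
    def meta(self) -> GridMeta:
        return self.spec.meta

    @property
    def years(self) -> np.ndarray:
        return self.spec.years


def _smooth_field(rng: np.random.Generator, shape, sd: float, length_scale: float) -> np.ndarray:
    """Spatially autocorrelated field: Gaussian-filtered white noise rescaled
    to the requested SD (mean 0)."""
    white = rng.standard_normal(shape)
    if length_scale > 0:
        f = ndimage.gaussian_filter(white, sigma=length_scale, mode="reflect")
    else:
        f = white
    s = f.std()
    if s > 0:
        f = f / s
    return f * sd


def generate_world(spec: WorldSpec) -> SyntheticWorld:
    """Generate the full synthetic study system, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    years = spec.years
    ny = len(years)
    shape = (spec.rows, spec.cols)
    mid = 0.5 * (spec.baseline_start + spec.baseline_end)

    baseline_fields: dict[str, np.ndarray] = {}
    annual: dict[str, np.ndarray] = {}
    for name in GENERATED:
        v = spec.variables[name]
        base = v.mean + _smooth_field(rng, shape, v.spatial_sd, v.length_scale)
        if v.floor is not None:
            base = np.maximum(base, v.floor)
        baseline_fields[name] = base
        # annual history: baseline + centred linear trend + spatially smoothed
        # interannual noise (climate years are coherent in space)
        noise = np.stack(
            [_smooth_field(rng, shape, v.noise_sd, v.length_scale / 2) for _ in range(ny)]
        ) if v.noise_sd > 0 else np.zeros((ny, *shape))
        series = base[None] + v.trend * (years - mid)[:, None, None] + noise
        if v.floor is not None:
            series = np.maximum(series, v.floor)
        annual[name] = series

    annual["aridity"] = annual["precipitation"] / annual["pet"]
    baseline_fields["aridity"] = baseline_fields["precipitation"] / baseline_fields["pet"]

    # grassland mask from an independent smooth field, thresholded at the
    # requested coverage fraction
    mask_field = _smooth_field(rng, shape, 1.0, 4.0)
    thr = np.quantile(mask_field, 1.0 - spec.mask_fraction)
    mask = mask_field >= thr

    # anomalies of the generated annual climate against its own baseline mean
    in_window = (years >= spec.baseline_start) & (years <= spec.baseline_end)
    anomalies: dict[str, np.ndarray] = {}
    for name in VARIABLES:
        normal = annual[name][in_window].mean(axis=0)
        anomalies[name] = feat.compute_anomaly(name, annual[name], normal[None])

    # baseline productivity surface and the anomaly-modulated response
    b = baseline_productivity(spec, baseline_fields["precipitation"], baseline_fields["temperature"])
    mult = np.ones((ny, *shape))
    for name, s in spec.sensitivity.items():
        if s:
            mult = mult + s * anomalies[name]
    mult = np.maximum(mult, spec.response_floor)
    anpp = b[None] * mult
    if spec.process_noise_sd > 0:
        anpp = anpp + rng.normal(0.0, spec.process_noise_sd, anpp.shape)
    anpp = np.maximum(anpp, 0.0)

    mean_anpp = anpp[in_window].mean(axis=0)

    meta = spec.meta
    monthly: dict[str, xr.DataArray] = {}
    for name in GENERATED:
        v = spec.variables[name]
        jit = (
            rng.normal(0.0, v.monthly_jitter_sd, (ny, 12, *shape))
            if v.monthly_jitter_sd > 0
            else 0.0
        )
        if name in ("precipitation", "pet"):
            m = annual[name][:, None] * _SUM_WEIGHTS[None, :, None, None] + jit
            m = np.maximum(m, 0.0)
        else:
            m = (
                annual[name][:, None]
                + v.seasonal_amplitude * _SEASON_OFFSET[None, :, None, None]
                + jit
            )
        monthly[name] = monthly_cube(m, years, meta)
    # aridity cube derived cellwise so the ratio identity holds exactly
    monthly["aridity"] = monthly["precipitation"] / np.maximum(monthly["pet"], 1e-9)

    return SyntheticWorld(
        spec=spec,
        monthly=monthly,
        annual_truth={k: annual_cube(v, years, meta) for k, v in annual.items()},
        true_anomalies={k: annual_cube(v, years, meta) for k, v in anomalies.items()},
        baseline_fields=baseline_fields,
        anpp=annual_cube(anpp, years, meta),
        mean_anpp=mean_anpp,
        mask=mask,
    )


def baseline_productivity(spec: WorldSpec, precip: np.ndarray, temp: np.ndarray) -> np.ndarray:
    """Smooth positive baseline ANPP surface: Michaelis–Menten in baseline
    precipitation, exponential tilt in baseline temperature."""
    sat = precip / (precip + spec.precip_half_saturation)
    tilt = np.exp(spec.temperature_gain * (temp - spec.temperature_ref))
    return spec.anpp_max * sat * tilt


def true_response(world: SyntheticWorld, row, col, year) -> np.ndarray:
    """Closed-form truth lookup used by tests and noise-free sampling."""
    yi = np.searchsorted(world.years, np.asarray(year))
    return world.anpp.values[yi, row, col]


def sample_sites(
    world: SyntheticWorld,
    n_sites: int,
    obs_per_site: int = 1,
    obs_noise_sd: float = 25.0,
    seed: int = 0,
    year_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Draw noisy field observations at distinct masked cells.

    Each site contributes ``obs_per_site`` records in distinct random years;
    observed ANPP is truth plus Gaussian noise, floored at zero.  Returns a
    table with columns site_id, lon, lat, year, anpp_g_m2.
    """
    if obs_noise_sd < 0:
        raise ValueError("observation noise SD must be >= 0")
    cells = np.flatnonzero(world.mask.ravel())
    if n_sites > cells.size:
        raise ValueError(f"requested {n_sites} sites but the mask has only {cells.size} cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(cells, size=n_sites, replace=False)
    rows, cols = np.unravel_index(chosen, world.mask.shape)
    meta = world.meta
    lons = meta.lon_centers()[cols]
    lats = meta.lat_centers()[rows]

    years = world.years
    if year_range is not None:
        years = years[(years >= year_range[0]) & (years <= year_range[1])]
    if obs_per_site > years.size:
        raise ValueError("obs_per_site exceeds the number of available years")

    recs = []
    for s in range(n_sites):
        ys = rng.choice(years, size=obs_per_site, replace=False)
        for y in np.sort(ys):
            truth = true_response(world, rows[s], cols[s], int(y))
            obs = truth if obs_noise_sd == 0 else max(truth + rng.normal(0, obs_noise_sd), 0.0)
            recs.append((s, lons[s], lats[s], int(y), float(obs)))
    return pd.DataFrame(recs, columns=["site_id", "lon", "lat", "year", "anpp_g_m2"])


def make_reference_npp(
    world: SyntheticWorld,
    anpp_fraction: float | np.ndarray = 0.5,
    extra_noise_sd: float = 20.0,
    seed: int = 0,
) -> xr.DataArray:
    """Reference NPP series: truth scaled by a temporally stable ANPP/NPP
    ratio, plus independent noise.  Stands in for satellite/DGVM products in
    temporal-validation exercises."""
    frac = np.asarray(anpp_fraction, dtype=float)
    if np.any(frac <= 0) or np.any(frac > 1):
        raise ValueError("ANPP/NPP fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    npp = world.anpp.values / frac
    if extra_noise_sd > 0:
        npp = npp + rng.normal(0.0, extra_noise_sd, npp.shape)
    out = annual_cube(npp, world.years, world.meta)
    off = ~world.mask
    out.values[:, off] = np.nan
    return out


def simulate_climate_model(
    world: SyntheticWorld,
    model_id: str,
    scenario: str,
    future_end: int = 2100,
    additive_bias: dict[str, float] | None = None,
    multiplicative_bias: dict[str, float] | None = None,
    extra_trend: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, xr.DataArray]:
    """Emulate one biased climate-model run over history plus a scenario era.

    History replays the world's generated monthly climate with per-variable
    constant additive/multiplicative biases and fresh interannual noise; the
    scenario era extrapolates each variable's trend (optionally steepened via
    ``extra_trend``, per year).  Output cubes cover ``year_start..future_end``
    for the four generated variables, ready for quantile-delta-mapping
    correction against the world's "observed" series.
    """
    spec = world.spec
    add = additive_bias or {}
    mul = multiplicative_bias or {}
    xtr = extra_trend or {}
    rng = np.random.default_rng(seed)
    years = np.arange(spec.year_start, future_end + 1)
    ny = len(years)
    shape = (spec.rows, spec.cols)
    mid = 0.5 * (spec.baseline_start + spec.baseline_end)
    last = spec.year_end

    out: dict[str, xr.DataArray] = {}
    for name in GENERATED:
        v = spec.variables[name]
        base = world.baseline_fields[name]
        trend = v.trend + xtr.get(name, 0.0)
        noise = (
            np.stack([_smooth_field(rng, shape, v.noise_sd, v.length_scale / 2) for _ in range(ny)])
            if v.noise_sd > 0
            else np.zeros((ny, *shape))
        )
        drift = np.where(years <= last, v.trend * (years - mid), v.trend * (last - mid) + trend * (years - last))
        series = base[None] + drift[:, None, None] + noise
        series = series * mul.get(name, 1.0) + add.get(name, 0.0)
        if v.floor is not None:
            series = np.maximum(series, v.floor)
        jit = (
            rng.normal(0.0, v.monthly_jitter_sd, (ny, 12, *shape))
            if v.monthly_jitter_sd > 0
            else 0.0
        )
        if name in ("precipitation", "pet"):
            m = series[:, None] * _SUM_WEIGHTS[None, :, None, None] + jit
            m = np.maximum(m, 0.0)
        else:
            m = series[:, None] + v.seasonal_amplitude * _SEASON_OFFSET[None, :, None, None] + jit
        out[name] = monthly_cube(m, years, spec.meta)
    logger.debug("simulated model %s under %s through %d", model_id, scenario, future_end)
    return out


def quiet_spec(**overrides) -> WorldSpec:
    """A WorldSpec with all temporal forcing off (no trend, no noise, zero
    sensitivity) — handy for degenerate-case tests."""
    variables = {
        k: replace(v, noise_sd=0.0, trend=0.0, monthly_jitter_sd=0.0)
        for k, v in _DEFAULT_VARIABLES.items()
    }
    sens = {k: 0.0 for k in VARIABLES}
    base = dict(variables=variables, sensitivity=sens, process_noise_sd=0.0)
    base.update(overrides)
    return WorldSpec(**base)
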
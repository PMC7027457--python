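"""Synthetic study landscapes and weather with known ground truth.

The real driving data for this kind of study (national met-office grids,
regional climate-model runs, field thermochron loggers) are access
restricted, so every input is emulated here with the structure the models
need and with ground truth that downstream calibrations must recover:

* a DEM with a coastline along the southern edge and two enclosed interior
  bowls (so basin delineation, pour-point routing and cold-air-pooling
  covariates are all exercised);
* spatially coherent daily weather per coarse cell — seasonal sinusoid plus
  AR(1) noise for temperature, clear-sky-bounded shortwave, a two-state
  Markov occurrence chain with gamma amounts for precipitation — where
  "projection" runs add a configurable warming trend and per-variable bias;
* logger series generated through the forward anomaly model with known
  coupling coefficients plus Gaussian sensor noise.

Every generator draws from its own RNG stream seeded by (master seed,
generator name), so adding one generator never perturbs another, and a
fixed seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import zlib

import numpy as np
import pandas as pd

from . import radiation
from .microclimate import CouplingCoefficients, predict_anomaly
from .rasters import DAILY_COLUMNS, LandSeaMask, LoggerSeries, RasterGrid

__all__ = ["FixtureConfig", "LoggerFixture", "gen_dem", "gen_weather_series",
           "gen_logger_obs", "clear_sky_daily_total"]


@dataclasses.dataclass
class FixtureConfig:
    """Knobs of the synthetic landscape and weather; defaults match the
    study conditions (maritime temperate, ~50 N, 12 km coarse cells)."""

    seed: int = 0
    nx: int = 32
    ny: int = 32
    cell_size: float = 100.0
    years: tuple[int, ...] = (2001, 2002)
    n_runs: int = 2
    coupling_truth: CouplingCoefficients = CouplingCoefficients(0.01, 1.0, 0.0)
    max_elev: float = 120.0
    lat: float = 50.0
    lon: float = -5.2
    origin_x: float = 170_000.0
    origin_y: float = 30_000.0
    # coarse climate grid
    n_coarse: int = 4                 # coarse grid is n_coarse x n_coarse
    coarse_cell: float = 12_000.0
    # weather statistics
    tmean_annual: float = 11.0        # degC
    t_seasonal_amp: float = 5.5       # degC
    t_diurnal_range: float = 6.0      # tmax - tmin, degC
    t_ar1: float = 0.7
    t_noise_sd: float = 1.8
    lapse: float = -0.006             # degC per m, coarse-cell offsets
    p_wet_given_wet: float = 0.6
    p_wet_given_dry: float = 0.25
    gamma_shape: float = 0.8
    gamma_mean_mm: float = 6.0
    wind_mean: float = 4.5
    # projection-run modifications
    trend_c_per_decade: float = 0.5
    bias: dict | None = None          # e.g. {"tmax": +1.2, "swdown": -2.0}
    logger_noise_sd: float = 0.0
    n_loggers: int = 8

    def rng(self, name: str) -> np.random.Generator:
        """Independent RNG stream for one generator."""
        return np.random.default_rng([self.seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Terrain


def gen_dem(cfg: FixtureConfig) -> tuple[RasterGrid, LandSeaMask]:
    """Synthetic coastal DEM: sea along the southern edge, terrain rising
    inland, gentle correlated hills, and two enclosed bowls whose saddle
    makes the higher one drain into the lower."""
    if cfg.nx < 16 or cfg.ny < 16:
        raise ValueError("DEM fixture needs nx, ny >= 16")
    rng = cfg.rng("dem")
    ny, nx = cfg.ny, cfg.nx
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    u = jj / (nx - 1)          # 0 west -> 1 east
    v = 1.0 - ii / (ny - 1)    # 0 south -> 1 north (row 0 is north)

    base = (v - 0.15) / 0.85 * cfg.max_elev  # negative over the southern strip
    # low-frequency hills from a few random cosines
    hills = np.zeros((ny, nx))
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        hills += rng.uniform(0.03, 0.08) * cfg.max_elev * np.cos(
            2 * np.pi * fx * u + ph1) * np.cos(2 * np.pi * fy * v + ph2)
    z = base + hills

    def carve_bowl(cu, cv, radius, depth):
        r = np.hypot(u - cu, (v - cv) * ny / nx)
        return -depth * np.exp(-(r / radius) ** 2)

    # two bowls: the western one higher, so its saddle spills east
    z += carve_bowl(0.30, 0.62, 0.10, 0.35 * cfg.max_elev)
    z += carve_bowl(0.62, 0.55, 0.12, 0.45 * cfg.max_elev)

    sea = z < 0
    # guarantee sea along the full southern edge
    sea[-1, :] = True
    z = np.where(sea, np.nan, np.clip(z, 0.0, cfg.max_elev))
    dem = RasterGrid(z.astype(np.float32), cfg.origin_x, cfg.origin_y, cfg.cell_size)
    mask = LandSeaMask(np.where(sea, 0.0, 1.0).astype(np.float32),
                       cfg.origin_x, cfg.origin_y, cfg.cell_size)
    return dem, mask


# ---------------------------------------------------------------------------
# Weather


_CEILING_MEMO: dict[tuple[float, float, int], np.ndarray] = {}


def clear_sky_daily_total(lat: float, lon: float, year: int) -> np.ndarray:
    """Clear-sky daily shortwave total (MJ m-2 day-1) per day of ``year``."""
    key = (round(lat, 4), round(lon, 4), year)
    if key in _CEILING_MEMO:
        return _CEILING_MEMO[key]
    days = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31), freq="D")
    out = np.empty(len(days))
    for k, d in enumerate(days):
        total = 0.0
        for h in range(24):
            t = dt.datetime(d.year, d.month, d.day, h, 30, tzinfo=dt.timezone.utc)
            total += radiation.clear_sky_radiation(lat, lon, t) * 3600e-6
        out[k] = total
    _CEILING_MEMO[key] = out
    return out


def markov_stationary_wet_prob(p_ww: float, p_wd: float) -> float:
    """Stationary wet-day probability of the 2-state occurrence chain."""
    return p_wd / (1.0 - p_ww + p_wd)


def gen_weather_series(cfg: FixtureConfig, kind: str = "observed",
                       run: int = 0) -> dict[tuple[int, int], pd.DataFrame]:
    """Daily weather per coarse cell, sharing one regional signal.

    ``kind`` is ``"observed"`` or ``"projection"``; projection runs add the
    configured linear warming trend and per-variable additive bias.
    Neighbouring coarse cells differ only through small elevation-lapse
    offsets, so the field is spatially coherent by construction.
    """
    if kind not in ("observed", "projection"):
        raise ValueError("kind must be 'observed' or 'projection'")
    if not cfg.years:
        raise ValueError("years must be non-empty")
    rng = cfg.rng(f"weather-{kind}-{run}")
    dates = pd.date_range(dt.date(cfg.years[0], 1, 1),
                          dt.date(cfg.years[-1], 12, 31), freq="D")
    nd = len(dates)
    doy = dates.dayofyear.to_numpy()
    yfrac = (dates.year - cfg.years[0]).to_numpy() + doy / 365.25

    # regional temperature: seasonal sinusoid + AR(1) noise
    seasonal = cfg.tmean_annual - cfg.t_seasonal_amp * np.cos(
        2 * np.pi * (doy - 15) / 365.25)
    eps = np.empty(nd)
    e = 0.0
    innov = rng.normal(0.0, cfg.t_noise_sd * np.sqrt(1 - cfg.t_ar1**2), nd)
    for k in range(nd):
        e = cfg.t_ar1 * e + innov[k]
        eps[k] = e
    tmean = seasonal + eps
    if kind == "projection":
        tmean = tmean + cfg.trend_c_per_decade * yfrac / 10.0

    # precipitation occurrence (2-state Markov) + gamma amounts, regional
    wet = np.empty(nd, dtype=bool)
    uu = rng.uniform(size=nd)
    prev = rng.uniform() < markov_stationary_wet_prob(cfg.p_wet_given_wet,
                                                      cfg.p_wet_given_dry)
    for k in range(nd):
        pw = cfg.p_wet_given_wet if prev else cfg.p_wet_given_dry
        wet[k] = uu[k] < pw
        prev = wet[k]
    amounts = rng.gamma(cfg.gamma_shape,
                        cfg.gamma_mean_mm / cfg.gamma_shape, nd)
    precip = np.where(wet, amounts, 0.0)

    # shortwave: clear-sky ceiling scaled by a cloudiness factor tied to rain
    ceilings = {y: clear_sky_daily_total(cfg.lat, cfg.lon, y) for y in set(dates.year)}
    ceiling = np.concatenate([ceilings[y] for y in sorted(set(dates.year))])[:nd]
    cloud = np.clip(rng.beta(2.0, 2.0, nd) + 0.25 * wet, 0.05, 0.95)
    swdown = ceiling * (1.0 - 0.75 * cloud)

    wind = np.clip(rng.gamma(4.0, cfg.wind_mean / 4.0, nd), 0.3, None)
    pres = 101.3 + rng.normal(0.0, 0.8, nd)
    # humidity from a plausible relative humidity at tmean
    rh = np.clip(rng.normal(0.8, 0.07, nd) + 0.05 * wet, 0.35, 0.99)
    es = 0.6108 * np.exp(17.27 * tmean / (tmean + 237.3))
    shum = np.clip(0.622 * rh * es / (pres - 0.378 * rh * es), 1e-4, 0.099)

    half_range = 0.5 * cfg.t_diurnal_range * (0.7 + 0.6 * (1 - cloud))

    bias = dict(cfg.bias or {}) if kind == "projection" else {}
    elev_offsets = _coarse_elevations(cfg)
    out: dict[tuple[int, int], pd.DataFrame] = {}
    for (ci, cj), elev in elev_offsets.items():
        dT = cfg.lapse * elev
        df = pd.DataFrame({
            "tmax": tmean + half_range + dT + bias.get("tmax", 0.0),
            "tmin": tmean - half_range + dT + bias.get("tmin", 0.0),
            "swdown": np.clip(swdown + bias.get("swdown", 0.0), 0.0, None),
            "shum": np.clip(shum + bias.get("shum", 0.0), 1e-4, 0.099),
            "pres": pres + bias.get("pres", 0.0),
            "wind": np.clip(wind + bias.get("wind", 0.0), 0.0, None),
            "precip": np.clip(precip * (1.0 + bias.get("precip_frac", 0.0)), 0.0, None),
        }, index=dates)[list(DAILY_COLUMNS)]
        out[(ci, cj)] = df
    return out


def _coarse_elevations(cfg: FixtureConfig) -> dict[tuple[int, int], float]:
    """Mean elevation per coarse cell: a smooth deterministic gradient so the
    lapse-rate structure is known exactly."""
    out = {}
    n = cfg.n_coarse
    for ci in range(n):
        for cj in range(n):
            # rises away from the (southern) coast and toward the east
            out[(ci, cj)] = 20.0 + 140.0 * (n - 1 - ci) / max(n - 1, 1) \
                + 30.0 * cj / max(n - 1, 1)
    return out


def coarse_cell_centers(cfg: FixtureConfig) -> dict[tuple[int, int], tuple[float, float]]:
    """Map coordinates of the coarse climate-grid cell centres; the fine
    raster sits inside the south-western coarse cells."""
    out = {}
    for ci in range(cfg.n_coarse):
        for cj in range(cfg.n_coarse):
            x = cfg.origin_x - cfg.coarse_cell + (cj + 0.5) * cfg.coarse_cell
            y = cfg.origin_y + cfg.coarse_cell - (ci + 0.5) * cfg.coarse_cell
            out[(ci, cj)] = (x, y)
    return out


# ---------------------------------------------------------------------------
# Loggers


@dataclasses.dataclass
class LoggerFixture:
    """Synthetic loggers plus the exact forcing used to generate them."""

    loggers: list[LoggerSeries]
    reference: pd.DataFrame  # mesoclimate reference temperature per site
    rnet: pd.DataFrame       # net radiation per site (W m-2)
    u_z: pd.DataFrame        # wind at sensor height per site (m s-1)
    sites: list[tuple[int, int]]
    truth: CouplingCoefficients


def gen_logger_obs(cfg: FixtureConfig, dem: RasterGrid, mask: LandSeaMask,
                   hourly: pd.DataFrame, height_m: float = 0.05) -> LoggerFixture:
    """Generate logger series through the forward anomaly model.

    Site cells are stratified across slope/aspect classes of the DEM (all on
    land; a site on a sea cell is an error by construction).  Each site's
    net radiation is computed from the hourly weather and its terrain, wind
    is height-adjusted with the site's shelter coefficient, and the logger
    temperature is reference + anomaly(coupling_truth) + N(0, sigma).
    """
    from . import radiation as rad

    rng = cfg.rng("loggers")
    tl = rad.terrain_layers(dem, n_dir=8)
    land_cells = np.transpose(np.nonzero(mask.land))
    if land_cells.size == 0:
        raise ValueError("no land cells for logger placement")

    # stratify: 2 slope classes x 4 aspect sectors
    slope_med = np.median(tl.slope[mask.land])
    classes: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for i, j in land_cells:
        sc = int(tl.slope[i, j] > slope_med)
        ac = int(tl.aspect[i, j] // 90) % 4
        classes.setdefault((sc, ac), []).append((i, j))
    sites: list[tuple[int, int]] = []
    keys = sorted(classes)
    k = 0
    while len(sites) < cfg.n_loggers:
        pool = classes[keys[k % len(keys)]]
        cand = pool[rng.integers(len(pool))]
        if cand not in sites:
            sites.append(cand)
        k += 1
    for (i, j) in sites:
        if not mask.land[i, j]:
            raise ValueError(f"logger site ({i}, {j}) fell on a sea cell")

    idx = hourly.index
    ref = {}
    rnet = {}
    uz = {}
    obs = {}
    lat, lon = cfg.lat, cfg.lon
    cos_z_cache = {}
    elev = np.nan_to_num(dem.values.astype(float), nan=0.0)
    for s, (i, j) in enumerate(sites):
        col = f"site{s}"
        # mesoclimate reference: hourly temp with an elevation lapse offset
        ref_t = hourly["temp"].to_numpy() + cfg.lapse * elev[i, j]
        sub_tl = _cell_layers(tl, i, j)
        rn = np.empty(len(idx))
        ratio = 0.7  # cloudiness carried overnight from the previous afternoon
        sw_arr = hourly["swrad"].to_numpy()
        sh_arr = hourly["shum"].to_numpy()
        pr_arr = hourly["pres"].to_numpy()
        for k2, ts in enumerate(idx):
            if ts not in cos_z_cache:
                pyts = ts.to_pydatetime()
                cos_z_cache[ts] = (rad.solar_position(lat, lon, pyts),
                                   rad.clear_sky_radiation(lat, lon, pyts))
            sp, cs = cos_z_cache[ts]
            sw = float(sw_arr[k2])
            swnet = rad.shortwave_on_surface(sw, sp, sub_tl, clear_sky=cs)[0, 0]
            if cs > 50.0:
                ratio = min(sw / cs, 1.0)
            rn[k2] = rad.net_radiation(swnet, ref_t[k2], float(sh_arr[k2]),
                                       float(pr_arr[k2]), ratio, sub_tl)[0, 0]
        shl = tl.shelter_toward(225.0)[i, j]
        u = rad.wind_at_height(hourly["wind"].to_numpy(), height_m, 0.01, shl)
        noise = rng.normal(0.0, cfg.logger_noise_sd, len(idx)) \
            if cfg.logger_noise_sd > 0 else 0.0
        temp = ref_t + predict_anomaly(rn, u, cfg.coupling_truth) + noise
        ref[col] = ref_t
        rnet[col] = rn
        uz[col] = u
        obs[col] = temp

    x, y = dem.cell_centers()
    loggers = [
        LoggerSeries(x=float(x[i, j]), y=float(y[i, j]), height_m=height_m,
                     records=pd.Series(obs[f"site{s}"], index=idx),
                     site_id=f"site{s}")
        for s, (i, j) in enumerate(sites)
    ]
    mk = lambda d: pd.DataFrame(d, index=idx)
    return LoggerFixture(loggers=loggers, reference=mk(ref), rnet=mk(rnet),
                         u_z=mk(uz), sites=sites, truth=cfg.coupling_truth)


def _cell_layers(tl, i: int, j: int):
    """A 1x1 TerrainLayers view of one cell (keeps the array interfaces)."""
    from .radiation import TerrainLayers

    return TerrainLayers(
        slope=tl.slope[i:i + 1, j:j + 1], aspect=tl.aspect[i:i + 1, j:j + 1],
        horizon=tl.horizon[:, i:i + 1, j:j + 1],
        sky_view=tl.sky_view[i:i + 1, j:j + 1],
        canopy=tl.canopy[i:i + 1, j:j + 1],
        shelter=tl.shelter[:, i:i + 1, j:j + 1],
        horizon_dirs=tl.horizon_dirs, shelter_dirs=tl.shelter_dirs,
    )
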
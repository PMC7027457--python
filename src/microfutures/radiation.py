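"""Solar geometry, terrain- and canopy-adjusted radiation, and wind profiles.

These are the physical drivers of the near-surface energy balance: net
shortwave on an inclined, possibly shaded surface; net longwave with a
vapour-pressure clear-sky emissivity and a cloud correction in the FAO-56
form; and the logarithmic wind-height profile with a topographic shelter
coefficient (after Ryan 1977).
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np

from .rasters import RasterGrid

__all__ = [
    "SolarPosition",
    "TerrainLayers",
    "solar_position",
    "solar_declination",
    "daylength_hours",
    "sunrise_sunset_hours",
    "clear_sky_radiation",
    "terrain_layers",
    "shortwave_on_surface",
    "net_radiation",
    "cloud_fraction_from_sw",
    "wind_at_height",
    "ryan_shelter",
]

SOLAR_CONSTANT = 1361.0  # W m-2
STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4


@dataclasses.dataclass(frozen=True)
class SolarPosition:
    zenith: float      # degrees, 0 = overhead
    azimuth: float     # degrees clockwise from north
    eqtime_min: float  # equation of time, minutes

    @property
    def elevation(self) -> float:
        return 90.0 - self.zenith

    @property
    def up(self) -> bool:
        return self.zenith < 90.0


def _fractional_year(t: dt.datetime) -> float:
    """Fractional year angle gamma (radians) for the NOAA low-accuracy algorithm."""
    doy = t.timetuple().tm_yday
    hours = t.hour + t.minute / 60 + t.second / 3600
    return 2 * np.pi / 365 * (doy - 1 + (hours - 12) / 24)


def solar_declination(t: dt.datetime) -> float:
    """Solar declination (degrees) from the NOAA Fourier expansion."""
    g = _fractional_year(t)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return float(np.degrees(decl))


def _equation_of_time(t: dt.datetime) -> float:
    g = _fractional_year(t)
    return float(
        229.18
        * (
            0.000075
            + 0.001868 * np.cos(g)
            - 0.032077 * np.sin(g)
            - 0.014615 * np.cos(2 * g)
            - 0.040849 * np.sin(2 * g)
        )
    )


def solar_position(lat: float, lon: float, timestamp: dt.datetime) -> SolarPosition:
    """NOAA-style solar zenith and azimuth; accuracy well under 0.5 degrees.

    ``timestamp`` must be timezone-aware UTC.
    """
    if timestamp.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware UTC")
    t = timestamp.astimezone(dt.timezone.utc)
    eqtime = _equation_of_time(t)
    decl = np.radians(solar_declination(t))
    utc_hours = t.hour + t.minute / 60 + t.second / 3600
    tst = utc_hours * 60 + eqtime + 4 * lon  # true solar time, minutes
    ha = np.radians(tst / 4 - 180)  # hour angle
    latr = np.radians(lat)
    cos_zen = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(ha)
    zen = np.arccos(np.clip(cos_zen, -1, 1))
    # azimuth clockwise from north; afternoon (ha > 0) mirrors to the west
    denom = np.cos(latr) * np.sin(zen)
    if abs(denom) < 1e-12:
        azimuth = 0.0
    else:
        cos_az = (np.sin(decl) - np.sin(latr) * np.cos(zen)) / denom
        az = float(np.degrees(np.arccos(np.clip(cos_az, -1, 1))))
        azimuth = (360.0 - az) if np.sin(ha) > 0 else az
    return SolarPosition(float(np.degrees(zen)), azimuth % 360.0, eqtime)


def daylength_hours(lat: float, t: dt.datetime) -> float:
    """Daylength (hours) from the sunset-hour-angle formula."""
    decl = np.radians(solar_declination(t))
    latr = np.radians(lat)
    cos_ws = -np.tan(latr) * np.tan(decl)
    if cos_ws <= -1 or cos_ws >= 1:
        raise ValueError("polar day/night daylength outside supported latitudes")
    ws = np.arccos(cos_ws)
    return float(24 / np.pi * ws)


def sunrise_sunset_hours(lat: float, lon: float, t: dt.datetime) -> tuple[float, float]:
    """Sunrise and sunset in UTC decimal hours for the date of ``t``."""
    noon = dt.datetime(t.year, t.month, t.day, 12, tzinfo=dt.timezone.utc)
    eqtime = _equation_of_time(noon)
    solar_noon_utc = 12 - lon / 15 - eqtime / 60
    half = daylength_hours(lat, noon) / 2
    return solar_noon_utc - half, solar_noon_utc + half


def clear_sky_radiation(lat: float, lon: float, timestamp: dt.datetime,
                        transmittance: float = 0.75) -> float:
    """Clear-sky global shortwave on a horizontal surface (W m-2)."""
    sp = solar_position(lat, lon, timestamp)
    if not sp.up:
        return 0.0
    cz = np.cos(np.radians(sp.zenith))
    return float(SOLAR_CONSTANT * transmittance * cz)


# ---------------------------------------------------------------------------
# Terrain layers


@dataclasses.dataclass
class TerrainLayers:
    """Per-cell static layers derived from the DEM (and optional canopy)."""

    slope: np.ndarray        # degrees
    aspect: np.ndarray       # degrees from north (downslope direction)
    horizon: np.ndarray      # (n_dir, ny, nx) horizon elevation angle, degrees
    sky_view: np.ndarray     # [0, 1]
    canopy: np.ndarray       # cover fraction [0, 1]
    shelter: np.ndarray      # (n_sector, ny, nx) Ryan shelter coefficient
    horizon_dirs: np.ndarray  # azimuths (deg from N) of the horizon rays
    shelter_dirs: np.ndarray  # azimuths of the shelter sectors

    def horizon_toward(self, azimuth: float) -> np.ndarray:
        k = int(np.argmin(np.abs((self.horizon_dirs - azimuth + 180) % 360 - 180)))
        return self.horizon[k]

    def shelter_toward(self, azimuth: float) -> np.ndarray:
        k = int(np.argmin(np.abs((self.shelter_dirs - azimuth + 180) % 360 - 180)))
        return self.shelter[k]


def _horn_slope_aspect(dem: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    """Slope and aspect by Horn's 3x3 finite differences (edge-replicated)."""
    z = np.pad(np.nan_to_num(dem, nan=0.0), 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)  # +y is north
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy))  # downslope bearing from N
    aspect = (aspect + 360) % 360
    return slope, aspect


def _horizon_angles(dem: np.ndarray, cell: float, n_dir: int,
                    max_dist_cells: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Horizon elevation angle (deg) per direction by ray marching."""
    ny, nx = dem.shape
    dirs = np.arange(n_dir) * 360.0 / n_dir
    z = np.nan_to_num(dem, nan=0.0)
    horizon = np.zeros((n_dir, ny, nx))
    ii, jj = np.mgrid[0:ny, 0:nx]
    for k, az in enumerate(dirs):
        azr = np.radians(az)
        dj = np.sin(azr)   # east component
        di = -np.cos(azr)  # row component (north = -row)
        best = np.full((ny, nx), -np.inf)
        for step in range(1, max_dist_cells + 1):
            si = np.rint(ii + di * step).astype(int)
            sj = np.rint(jj + dj * step).astype(int)
            valid = (si >= 0) & (si < ny) & (sj >= 0) & (sj < nx)
            zs = np.where(valid, z[np.clip(si, 0, ny - 1), np.clip(sj, 0, nx - 1)], -np.inf)
            ang = (zs - z) / (step * cell)
            best = np.maximum(best, ang)
        horizon[k] = np.degrees(np.arctan(np.clip(best, 0, None)))
    return horizon, dirs


def ryan_shelter(upwind_slope_deg: np.ndarray | float) -> np.ndarray | float:
    """Topographic shelter coefficient from the upwind inclination angle.

    The Ryan (1977) regression reduces valley-floor wind in proportion to the
    upwind terrain angle (degrees, uphill positive):
    ``S = 1 - 0.00882 * max(angle, 0)``, clipped to [0, 1].
    """
    ang = np.maximum(np.asarray(upwind_slope_deg, dtype=float), 0.0)
    return np.clip(1.0 - 0.00882 * ang, 0.0, 1.0)


def terrain_layers(dem: RasterGrid, canopy: RasterGrid | None = None,
                   n_dir: int = 24, n_shelter_sectors: int = 8) -> TerrainLayers:
    """Compute slope, aspect, horizon angles, sky-view, canopy and shelter.

    Sky-view factor is the mean over horizon directions of cos^2 of the
    horizon angle (isotropic-sky weighting).  The shelter coefficient per
    wind sector applies Ryan's regression to the upwind horizon angle of the
    sector nearest the wind's from-direction.
    """
    if dem.ny < 3 or dem.nx < 3:
        raise ValueError("DEM must be at least 3x3")
    z = dem.values.astype(np.float64)
    slope, aspect = _horn_slope_aspect(z, dem.cell_size)
    horizon, dirs = _horizon_angles(z, dem.cell_size, n_dir)
    sky_view = np.mean(np.cos(np.radians(horizon)) ** 2, axis=0)
    if canopy is not None:
        if not canopy.same_geometry(dem):
            raise ValueError("canopy raster must share the DEM geometry")
        cnp = np.clip(np.nan_to_num(canopy.values.astype(np.float64), nan=0.0), 0, 1)
    else:
        cnp = np.zeros_like(z)
    sector_dirs = np.arange(n_shelter_sectors) * 360.0 / n_shelter_sectors
    shelter = np.empty((n_shelter_sectors, dem.ny, dem.nx))
    for s, az in enumerate(sector_dirs):
        # wind from-direction az: upwind terrain lies toward az
        k = int(np.argmin(np.abs((dirs - az + 180) % 360 - 180)))
        shelter[s] = ryan_shelter(horizon[k])
    return TerrainLayers(
        slope=slope, aspect=aspect, horizon=horizon, sky_view=sky_view,
        canopy=cnp, shelter=shelter, horizon_dirs=dirs, shelter_dirs=sector_dirs,
    )


# ---------------------------------------------------------------------------
# Radiation on the surface


def erbs_diffuse_fraction(kt: np.ndarray | float) -> np.ndarray | float:
    """Diffuse fraction of global shortwave from the clearness index (Erbs)."""
    kt = np.asarray(kt, dtype=float)
    fd = np.where(
        kt <= 0.22,
        1.0 - 0.09 * kt,
        np.where(
            kt <= 0.80,
            0.9511 - 0.1604 * kt + 4.388 * kt**2 - 16.638 * kt**3 + 12.336 * kt**4,
            0.165,
        ),
    )
    return np.clip(fd, 0.0, 1.0)


def shortwave_on_surface(
    swrad: float,
    sp: SolarPosition,
    tl: TerrainLayers,
    albedo: float = 0.23,
    clear_sky: float | None = None,
) -> np.ndarray:
    """Net shortwave absorbed by each cell's surface (W m-2).

    The horizontal global flux is split into direct and diffuse with the
    Erbs clearness-index correlation, the direct beam is projected onto each
    cell's slope/aspect and removed where the sun sits below the local
    horizon, the diffuse part is scaled by sky-view, both are attenuated by
    canopy transmission (1 - cover), and the total by (1 - albedo).
    """
    if not (0.0 <= albedo <= 1.0):
        raise ValueError("albedo must be in [0, 1]")
    shape = tl.sky_view.shape
    if swrad <= 0 or not sp.up:
        return np.zeros(shape)
    cz = np.cos(np.radians(sp.zenith))
    if clear_sky is None:
        clear_sky = SOLAR_CONSTANT * 0.75 * cz
    kt = min(swrad / max(clear_sky / 0.75, 1e-9), 1.0)  # vs extraterrestrial
    fd = float(erbs_diffuse_fraction(kt))
    diffuse = swrad * fd
    direct_h = swrad - diffuse  # on the horizontal
    beam = direct_h / max(cz, 0.05)  # beam-normal, capped near the horizon
    zin = np.radians(sp.zenith)
    slr = np.radians(tl.slope)
    cos_inc = (np.cos(zin) * np.cos(slr)
               + np.sin(zin) * np.sin(slr) * np.cos(np.radians(sp.azimuth - tl.aspect)))
    cos_inc = np.clip(cos_inc, 0.0, None)
    blocked = tl.horizon_toward(sp.azimuth) > sp.elevation
    direct = np.where(blocked, 0.0, beam * cos_inc)
    transmission = 1.0 - tl.canopy
    total = (direct + diffuse * tl.sky_view) * transmission
    return (1.0 - albedo) * total


def cloud_fraction_from_sw(swrad: float, clear_sky: float) -> float:
    """Cloudiness proxy: 1 - received/clear-sky shortwave, clipped to [0, 1]."""
    if clear_sky <= 1e-6:
        return 0.0
    return float(np.clip(1.0 - swrad / clear_sky, 0.0, 1.0))


def fao56_net_longwave(temp_c: float, ea_kpa: float, sw_ratio: float) -> float:
    """FAO-56 net outgoing longwave (W m-2) for a horizontal surface.

    ``sw_ratio`` is received/clear-sky shortwave (the cloudiness term),
    clipped to [0.3, 1].
    """
    tk = temp_c + 273.16
    f_cloud = 1.35 * np.clip(sw_ratio, 0.3, 1.0) - 0.35
    emis = 0.34 - 0.14 * np.sqrt(max(ea_kpa, 0.0))
    return float(STEFAN_BOLTZMANN * tk**4 * emis * f_cloud)


def vapour_pressure_kpa(shum: float, pres_kpa: float) -> float:
    """Actual vapour pressure (kPa) from specific humidity and pressure."""
    return shum * pres_kpa / (0.622 + 0.378 * shum)


def net_radiation(
    swnet: np.ndarray | float,
    temp: float,
    shum: float,
    pres: float,
    sw_ratio: float,
    tl: TerrainLayers | None = None,
) -> np.ndarray | float:
    """Net all-wave radiation: absorbed shortwave minus net longwave loss.

    The longwave term follows FAO-56 (vapour-pressure emissivity, cloud
    correction from the shortwave ratio, carried overnight by the caller)
    and is scaled by sky-view where terrain layers are given.
    """
    ea = vapour_pressure_kpa(shum, pres)
    lnet = fao56_net_longwave(temp, ea, sw_ratio)
    if tl is not None:
        lnet = lnet * tl.sky_view
    return swnet - lnet


# ---------------------------------------------------------------------------
# Wind


def wind_at_height(u_ref: float | np.ndarray, z_target: float, z0: float = 0.01,
                   shelter: float | np.ndarray = 1.0) -> float | np.ndarray:
    """Wind speed at ``z_target`` from the 2-m reference by the log profile.

    ``u(z) = shelter * u_ref * ln(z/z0) / ln(2/z0)``; never negative.
    """
    if z0 <= 0 or z_target <= z0:
        raise ValueError("require z_target > z0 > 0")
    scale = np.log(z_target / z0) / np.log(2.0 / z0)
    return np.maximum(np.asarray(shelter) * np.asarray(u_ref) * scale, 0.0)[()]
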
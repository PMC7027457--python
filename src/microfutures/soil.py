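"""Two-layer soil-moisture model over delineated hydrological basins.

A thin upper layer (default 0.05 m) supplies bare-soil evaporation; a deep
lower layer (default 0.95 m) stores the bulk of the water.  Each day,
per cell: curve-number runoff is removed from precipitation, the remainder
infiltrates the top layer (excess ponding in a surface store), actual
evapotranspiration is withdrawn (bare-soil share from the top layer only,
vegetation share split equally between layers), water moves between the
layers by van Genuchten diffusivity/conductivity driven by the moisture
difference plus a gravity term, and the deep layer drains at its hydraulic
conductivity.  Within each basin, water is then redistributed across cells
by topographic wetness index rank, and surface water beyond the basin's
holding capacity spills to the adjoining basin at the pour point, basins
processed from the highest pour point downwards.

No calibration enters anywhere: every term is computed from first
principles, so the daily water budget must close to machine accuracy — the
model's primary correctness check.
"""

from __future__ import annotations

import dataclasses
import heapq
import warnings

import numpy as np
import pandas as pd

from .rasters import LandSeaMask, RasterGrid

__all__ = [
    "SoilHydraulicParams",
    "SoilColumnState",
    "BasinMap",
    "LOAM",
    "vg_hydraulics",
    "vg_theta_at_psi",
    "wilting_point",
    "fao56_hourly_et",
    "reference_et",
    "curve_number_runoff",
    "adjust_cn_for_amc",
    "delineate_basins",
    "step_soil_day",
    "moisture_0_10cm",
    "SoilSimulation",
]


@dataclasses.dataclass(frozen=True)
class SoilHydraulicParams:
    """Van Genuchten soil hydraulic parameters.

    theta_r/theta_s: residual/saturated fractional water content;
    alpha (m-1) and n (-) shape the retention curve; k_sat is the saturated
    hydraulic conductivity in m/day.
    """

    theta_r: float
    theta_s: float
    alpha: float  # m-1
    n: float
    k_sat: float  # m day-1

    def __post_init__(self):
        if not (0 <= self.theta_r < self.theta_s <= 1):
            raise ValueError("require 0 <= theta_r < theta_s <= 1")
        if self.n <= 1 or self.alpha <= 0 or self.k_sat <= 0:
            raise ValueError("require n > 1, alpha > 0, k_sat > 0")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


#: a typical loam; the uniform-soil default for landscape runs
LOAM = SoilHydraulicParams(theta_r=0.078, theta_s=0.43, alpha=3.6, n=1.56, k_sat=0.2496)


@dataclasses.dataclass
class SoilColumnState:
    """Grid state: fractional water content per layer plus ponded surface water."""

    theta1: np.ndarray  # top layer
    theta2: np.ndarray  # deep layer
    d1: float = 0.05    # m
    d2: float = 0.95    # m
    surface_mm: np.ndarray | None = None

    def __post_init__(self):
        self.theta1 = np.asarray(self.theta1, dtype=np.float64)
        self.theta2 = np.asarray(self.theta2, dtype=np.float64)
        if self.surface_mm is None:
            self.surface_mm = np.zeros_like(self.theta1)

    def water_mm(self, land: np.ndarray) -> float:
        """Total stored water (mm summed over land cells)."""
        return float(
            (self.theta1[land] * self.d1 * 1000).sum()
            + (self.theta2[land] * self.d2 * 1000).sum()
            + self.surface_mm[land].sum()
        )

    def copy(self) -> "SoilColumnState":
        return SoilColumnState(self.theta1.copy(), self.theta2.copy(),
                               self.d1, self.d2, self.surface_mm.copy())


# ---------------------------------------------------------------------------
# Van Genuchten hydraulics


def vg_hydraulics(theta, p: SoilHydraulicParams):
    """Conductivity K (m/day), diffusivity D (m^2/day) and matric potential
    psi (m, negative = suction) at water content ``theta``.

    K follows Mualem-van Genuchten, ``K = k_sat * Se^0.5 * (1-(1-Se^{1/m})^m)^2``;
    D = K * d|psi|/dtheta with the analytic retention-curve derivative.
    """
    theta = np.asarray(theta, dtype=float)
    if (theta < p.theta_r - 1e-12).any() or (theta > p.theta_s + 1e-12).any():
        raise ValueError("theta outside [theta_r, theta_s]")
    se = np.clip((theta - p.theta_r) / (p.theta_s - p.theta_r), 0.0, 1.0)
    m = p.m
    K = p.k_sat * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    # retention curve: |psi| = (1/alpha) * (Se^{-1/m} - 1)^{1/n}
    se_c = np.clip(se, 1e-9, 1.0 - 1e-9)
    h = (1.0 / p.alpha) * (se_c ** (-1.0 / m) - 1.0) ** (1.0 / p.n)
    psi = -h
    # d|psi|/dSe, then /(theta_s - theta_r) for d|psi|/dtheta
    dh_dse = ((1.0 / p.alpha) * (1.0 / p.n)
              * (se_c ** (-1.0 / m) - 1.0) ** (1.0 / p.n - 1.0)
              * (1.0 / m) * se_c ** (-1.0 / m - 1.0))
    D = K * dh_dse / (p.theta_s - p.theta_r)
    D = np.where(se <= 0, 0.0, D)
    return K[()], D[()], psi[()]


def vg_theta_at_psi(psi_m: float, p: SoilHydraulicParams) -> float:
    """Water content at matric potential ``psi_m`` (m, negative) by the
    inverse retention curve."""
    h = abs(psi_m)
    se = (1.0 + (p.alpha * h) ** p.n) ** (-p.m)
    return p.theta_r + se * (p.theta_s - p.theta_r)


def wilting_point(p: SoilHydraulicParams) -> float:
    """Content at -150 m matric potential (-1500 kPa)."""
    return vg_theta_at_psi(-150.0, p)


# ---------------------------------------------------------------------------
# FAO-56 Penman-Monteith reference evapotranspiration

_GAMMA_COEFF = 0.000665  # psychrometric constant coefficient, kPa/(kPa degC)


def _sat_vp(t_c: float) -> float:
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def fao56_hourly_et(temp_c, rnet_wm2, shum, pres_kpa, wind2m, daytime=None):
    """Hourly FAO-56 Penman-Monteith reference ET (mm/hour), vectorised.

    Soil heat flux G = 0.1 Rn by day, 0.5 Rn by night (FAO-56 hourly rule).
    """
    t = np.asarray(temp_c, dtype=float)
    rn = np.asarray(rnet_wm2, dtype=float) * 3600e-6  # W m-2 -> MJ m-2 h-1
    u2 = np.asarray(wind2m, dtype=float)
    pres = np.asarray(pres_kpa, dtype=float)
    q = np.asarray(shum, dtype=float)
    if daytime is None:
        daytime = rn > 0
    g = np.where(daytime, 0.1, 0.5) * rn
    es = _sat_vp(t)
    ea = np.minimum(q * pres / (0.622 + 0.378 * q), es)
    delta = 4098.0 * es / (t + 237.3) ** 2
    gamma = _GAMMA_COEFF * pres
    num = 0.408 * delta * (rn - g) + gamma * (37.0 / (t + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return np.maximum(num / den, 0.0)


def reference_et(hourly: pd.DataFrame, rnet_wm2: np.ndarray) -> float:
    """Daily reference ET (mm/day): the 24 hourly Penman-Monteith values summed."""
    if len(hourly) != 24:
        raise ValueError(f"expected 24 hourly records, got {len(hourly)}")
    et = fao56_hourly_et(hourly["temp"].to_numpy(), np.asarray(rnet_wm2),
                         hourly["shum"].to_numpy(), hourly["pres"].to_numpy(),
                         hourly["wind"].to_numpy())
    return float(np.sum(et))


# ---------------------------------------------------------------------------
# Curve-number runoff


def adjust_cn_for_amc(cn: float, antecedent_5day_mm: float,
                      dry_mm: float = 12.7, wet_mm: float = 27.9) -> float:
    """Map the average-condition curve number to dry (AMC I) or wet (AMC III)
    equivalents from 5-day antecedent precipitation."""
    if antecedent_5day_mm < dry_mm:
        return 4.2 * cn / (10.0 - 0.058 * cn)
    if antecedent_5day_mm > wet_mm:
        return 23.0 * cn / (10.0 + 0.13 * cn)
    return cn


def curve_number_runoff(precip_mm, cn: float, amc_adjusted: bool = False,
                        antecedent_5day_mm: float = 0.0):
    """SCS curve-number storm runoff (mm).

    ``S = 25400/CN - 254`` (mm); initial abstraction ``Ia = 0.2 S``;
    ``Q = (P - Ia)^2 / (P + 0.8 S)`` for ``P > Ia`` else 0.
    """
    if not (30.0 <= cn <= 100.0):
        raise ValueError("curve number must lie in [30, 100]")
    if amc_adjusted:
        cn = min(adjust_cn_for_amc(cn, antecedent_5day_mm), 100.0)
    p = np.asarray(precip_mm, dtype=float)
    s = 25400.0 / cn - 254.0
    ia = 0.2 * s
    q = np.where(p > ia, (p - ia) ** 2 / (p + 0.8 * s), 0.0)
    return np.minimum(q, p)[()]


# ---------------------------------------------------------------------------
# Basin delineation, flow accumulation, TWI

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

OUTLET = 0  # basin id of the catchment draining off the land area


@dataclasses.dataclass
class BasinMap:
    """Basin labels, pour points and per-cell topographic wetness index."""

    labels: np.ndarray                 # int basin id per cell; -1 = not land
    pour_point: dict[int, tuple[int, int]]
    pour_elev: dict[int, float]
    downstream: dict[int, int | None]
    twi: np.ndarray

    @property
    def basin_ids(self) -> list[int]:
        return sorted(self.pour_point)

    def cells(self, basin_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == basin_id)

    def processing_order(self) -> list[int]:
        """Basin ids in descending pour-point elevation (highest first)."""
        return sorted(self.pour_point, key=lambda b: -self.pour_elev[b])


def _flow_dirs(z: np.ndarray, land: np.ndarray, cell: float) -> np.ndarray:
    """D8 steepest-descent direction index per cell; -1 = pit, -2 = drains out."""
    ny, nx = z.shape
    fd = np.full((ny, nx), -1, dtype=np.int8)
    for i in range(ny):
        for j in range(nx):
            if not land[i, j]:
                continue
            best_slope = 0.0
            best_k = -1
            drains_out = False
            for k, (di, dj) in enumerate(_D8):
                ni, nj = i + di, j + dj
                dist = cell * (np.sqrt(2.0) if di and dj else 1.0)
                if not (0 <= ni < ny and 0 <= nj < nx) or not land[ni, nj]:
                    # off the land area: treat as a drop to the outlet
                    slope = (z[i, j] - (z[i, j] - 1.0)) / dist
                    if slope > best_slope:
                        best_slope = slope
                        drains_out = True
                        best_k = k
                    continue
                slope = (z[i, j] - z[ni, nj]) / dist
                if slope > best_slope:
                    best_slope = slope
                    best_k = k
                    drains_out = False
            if best_k < 0:
                fd[i, j] = -1  # pit (or flat)
            elif drains_out:
                fd[i, j] = -2
            else:
                fd[i, j] = best_k
    _resolve_flats(z, land, fd)
    return fd


def _resolve_flats(z: np.ndarray, land: np.ndarray, fd: np.ndarray) -> None:
    """Drain flat areas toward any resolved equal-elevation neighbour (BFS),
    so only genuine depression bottoms remain pits."""
    from collections import deque

    ny, nx = z.shape
    queue = deque(zip(*np.nonzero((fd != -1) & land)))
    while queue:
        i, j = queue.popleft()
        for k, (di, dj) in enumerate(_D8):
            ni, nj = i + di, j + dj
            if not (0 <= ni < ny and 0 <= nj < nx):
                continue
            if land[ni, nj] and fd[ni, nj] == -1 and z[ni, nj] == z[i, j]:
                # neighbour (ni, nj) drains toward (i, j): reverse direction
                fd[ni, nj] = _D8.index((-di, -dj))
                queue.append((ni, nj))


def delineate_basins(dem: RasterGrid, mask: LandSeaMask | None = None) -> BasinMap:
    """Delineate depression basins, pour points and TWI from the DEM.

    Each interior depression (catchment of a pit) is one basin; all cells
    draining off the land area form the outlet basin (id 0, downstream
    None).  A basin's pour point is the lowest saddle on its boundary; its
    downstream basin is the neighbour receiving flow across that saddle.
    TWI is ``ln(a / tan beta)`` with D8 specific catchment area ``a`` and
    local slope floored at 0.001 rad.
    """
    z = dem.values.astype(np.float64)
    land = np.isfinite(z) if mask is None else (mask.land & np.isfinite(z))
    if not land.any():
        raise ValueError("DEM has no land cells")
    ny, nx = z.shape
    cell = dem.cell_size
    flat_input = np.ptp(z[land]) == 0
    # deterministic micro-tilt so symmetric bowls have one unique pit each
    ii, jj = np.mgrid[0:ny, 0:nx]
    z = z + 1e-9 * cell * (ii * nx + jj) / (ny * nx)
    fd = _flow_dirs(z, land, cell)
    if flat_input:
        warnings.warn("DEM is flat: all land drains to a single outlet basin",
                      stacklevel=2)

    # label by following flow to a pit or off the land area (path compression)
    labels = np.full((ny, nx), -1, dtype=np.int64)
    pit_label: dict[tuple[int, int], int] = {}
    next_label = OUTLET + 1
    for i in range(ny):
        for j in range(nx):
            if not land[i, j] or labels[i, j] != -1:
                continue
            path = []
            ci, cj = i, j
            lab = None
            while True:
                if labels[ci, cj] != -1:
                    lab = labels[ci, cj]
                    break
                path.append((ci, cj))
                k = fd[ci, cj]
                if k == -2:
                    lab = OUTLET
                    break
                if k == -1:
                    if (ci, cj) not in pit_label:
                        pit_label[(ci, cj)] = next_label
                        next_label += 1
                    lab = pit_label[(ci, cj)]
                    break
                di, dj = _D8[k]
                ci, cj = ci + di, cj + dj
            for (pi, pj) in path:
                labels[pi, pj] = lab

    # pour points: lowest boundary saddle per basin
    pour_point: dict[int, tuple[int, int]] = {}
    pour_elev: dict[int, float] = {}
    downstream: dict[int, int | None] = {}
    ids = sorted(set(labels[land].tolist()))
    for b in ids:
        best = (np.inf, None, None)
        for i, j in zip(*np.nonzero(labels == b)):
            for di, dj in _D8:
                ni, nj = i + di, j + dj
                outside = not (0 <= ni < ny and 0 <= nj < nx) or not land[ni, nj]
                if outside:
                    saddle = z[i, j]
                    nb = None
                else:
                    if labels[ni, nj] == b:
                        continue
                    saddle = max(z[i, j], z[ni, nj])
                    nb = int(labels[ni, nj])
                if saddle < best[0]:
                    best = (saddle, (int(i), int(j)), nb)
        pour_elev[b] = float(best[0])
        pour_point[b] = best[1]
        downstream[b] = best[2]
    if OUTLET in downstream:
        downstream[OUTLET] = None

    floor_elev = {b: float(z[labels == b].min()) for b in ids}
    _break_cycles(downstream, floor_elev)
    twi = _compute_twi(z, land, fd, cell)
    return BasinMap(labels=labels, pour_point=pour_point, pour_elev=pour_elev,
                    downstream=downstream, twi=twi)


def _break_cycles(downstream: dict[int, int | None], floor_elev: dict[int, float]) -> None:
    """Downstream pointers must be acyclic.  Two basins sharing an
    equal-elevation saddle point at each other; the one with the lower floor
    is the pair's true sink, so it keeps the water (downstream None)."""
    for b in list(downstream):
        seen = {b}
        cur = downstream[b]
        while cur is not None:
            if cur in seen:
                cut = min(seen | {cur}, key=lambda k: (floor_elev.get(k, 0.0), k))
                downstream[cut] = None
                break
            seen.add(cur)
            cur = downstream.get(cur)


def _compute_twi(z: np.ndarray, land: np.ndarray, fd: np.ndarray, cell: float) -> np.ndarray:
    ny, nx = z.shape
    acc = np.ones((ny, nx))
    order = np.argsort(z[land])[::-1]
    cells = np.transpose(np.nonzero(land))[order]
    for i, j in cells:
        k = fd[i, j]
        if k >= 0:
            di, dj = _D8[k]
            acc[i + di, j + dj] += acc[i, j]
    # local slope toward the steepest-descent neighbour
    tanb = np.full((ny, nx), 0.001)
    for i, j in np.transpose(np.nonzero(land)):
        k = fd[i, j]
        if k >= 0:
            di, dj = _D8[k]
            dist = cell * (np.sqrt(2.0) if di and dj else 1.0)
            tanb[i, j] = max((z[i, j] - z[i + di, j + dj]) / dist, 0.001)
        elif k == -2:
            tanb[i, j] = max(1.0 / cell, 0.001)
    a = acc * cell  # specific catchment area: cells * cell_area / cell width
    twi = np.where(land, np.log(a / tanb), np.nan)
    return twi


# ---------------------------------------------------------------------------
# Daily step


@dataclasses.dataclass
class DayBudget:
    """Whole-grid water accounting for one day (mm summed over land cells)."""

    precip: float
    runoff: float
    et_actual: float
    drainage: float
    export: float
    storage_start: float
    storage_end: float

    @property
    def closure_error(self) -> float:
        return (self.precip
                - (self.storage_end - self.storage_start)
                - self.runoff - self.et_actual - self.drainage - self.export)


def _twi_redistribute(w: np.ndarray, twi: np.ndarray, w_min: np.ndarray | float,
                      w_max: np.ndarray | float) -> np.ndarray:
    """Reallocate water within a basin so content increases with TWI.

    The target is linear in TWI quantile, conserves the basin total exactly
    and respects [w_min, w_max] bounds; clipped surplus is spread over
    unclipped cells until exhausted.
    """
    total = w.sum()
    n = w.size
    if n == 1:
        return w.copy()
    q = np.empty(n)
    q[np.argsort(twi, kind="stable")] = np.linspace(0.0, 1.0, n)
    lo = np.broadcast_to(np.asarray(w_min, dtype=float), w.shape).copy()
    hi = np.broadcast_to(np.asarray(w_max, dtype=float), w.shape).copy()
    mean = total / n
    # spread = half the available head-room, centred on the mean
    half = min(mean - lo.min(), hi.max() - mean)
    target = mean + (q - 0.5) * 2.0 * half * 0.5
    target = np.clip(target, lo, hi)
    # restore exact conservation after clipping
    for _ in range(50):
        diff = total - target.sum()
        if abs(diff) < 1e-12 * max(abs(total), 1.0):
            break
        if diff > 0:
            room = hi - target
            movable = room > 1e-15
            if not movable.any():
                break
            add = np.zeros(n)
            add[movable] = np.minimum(room[movable], diff / movable.sum())
            target += add
        else:
            room = target - lo
            movable = room > 1e-15
            if not movable.any():
                break
            take = np.zeros(n)
            take[movable] = np.minimum(room[movable], -diff / movable.sum())
            target -= take
    # final exact fix on the cell with most head-room (residual is microscopic)
    diff = total - target.sum()
    if diff != 0.0:
        k = int(np.argmax(hi - target)) if diff > 0 else int(np.argmax(target - lo))
        target[k] += diff
    return target


def step_soil_day(
    state: SoilColumnState,
    precip_mm: np.ndarray,
    pet_mm: np.ndarray,
    basins: BasinMap,
    p: SoilHydraulicParams = LOAM,
    cn: float = 75.0,
    bare_frac: float = 0.2,
    antecedent_5day_mm: float = 0.0,
    n_substeps: int = 24,
    max_surface_mm: float = 10.0,
    gravity: bool = True,
    redistribute: bool = True,
) -> tuple[SoilColumnState, DayBudget]:
    """Advance the soil state one day and return the closed water budget.

    The per-cell order of operations: curve-number runoff, infiltration,
    evapotranspiration (bare-soil from layer 1, vegetation split equally),
    sub-daily inter-layer exchange plus deep drainage, then per-basin TWI
    redistribution and pour-point overflow routing.
    """
    land = basins.labels >= 0
    new = state.copy()
    mm1 = state.d1 * 1000.0  # mm of water per unit theta, layer 1
    mm2 = state.d2 * 1000.0
    storage_start = state.water_mm(land)

    precip = np.where(land, np.asarray(precip_mm, dtype=float), 0.0)
    pet = np.where(land, np.asarray(pet_mm, dtype=float), 0.0)

    # (1) runoff
    runoff = np.where(land, curve_number_runoff(precip, cn, amc_adjusted=True,
                                                antecedent_5day_mm=antecedent_5day_mm), 0.0)
    # (2) infiltration of throughfall + yesterday's ponded water
    supply = precip - runoff + new.surface_mm
    new.surface_mm = np.zeros_like(new.surface_mm)
    room1 = (p.theta_s - new.theta1) * mm1
    infil = np.minimum(supply, room1)
    new.theta1 = new.theta1 + np.where(land, infil / mm1, 0.0)
    new.surface_mm = np.where(land, supply - infil, 0.0)

    # (3) evapotranspiration with linear stress below half available range
    stress_theta = p.theta_r + 0.5 * (p.theta_s - p.theta_r)

    def _stress(theta):
        return np.clip((theta - p.theta_r) / (stress_theta - p.theta_r), 0.0, 1.0)

    e_bare_dem = bare_frac * pet * _stress(new.theta1)
    e_bare = np.minimum(e_bare_dem, (new.theta1 - p.theta_r) * mm1)
    new.theta1 -= np.where(land, e_bare / mm1, 0.0)
    t_each = 0.5 * (1.0 - bare_frac) * pet
    t1 = np.minimum(t_each * _stress(new.theta1), (new.theta1 - p.theta_r) * mm1)
    new.theta1 -= np.where(land, t1 / mm1, 0.0)
    t2 = np.minimum(t_each * _stress(new.theta2), (new.theta2 - p.theta_r) * mm2)
    new.theta2 -= np.where(land, t2 / mm2, 0.0)
    et_actual = np.where(land, e_bare + t1 + t2, 0.0)

    # (4) inter-layer exchange + (5) deep drainage, sub-daily explicit steps
    dt = 1.0 / n_substeps
    dz = 0.5 * (state.d1 + state.d2)  # layer-centre separation, m
    drainage = np.zeros_like(new.theta1)
    for _ in range(n_substeps):
        t1c = np.clip(new.theta1, p.theta_r, p.theta_s)
        t2c = np.clip(new.theta2, p.theta_r, p.theta_s)
        tbar = 0.5 * (t1c + t2c)
        K, D, _ = vg_hydraulics(tbar, p)
        flux = D * (t1c - t2c) / dz  # m/day, downward positive
        if gravity:
            flux = flux + K
        flux_mm = flux * 1000.0 * dt
        # limit so neither layer leaves its physical range
        flux_mm = np.minimum(flux_mm, (t1c - p.theta_r) * mm1)
        flux_mm = np.minimum(flux_mm, (p.theta_s - t2c) * mm2)
        flux_mm = np.maximum(flux_mm, -(t2c - p.theta_r) * mm2)
        flux_mm = np.maximum(flux_mm, -(p.theta_s - t1c) * mm1)
        new.theta1 -= np.where(land, flux_mm / mm1, 0.0)
        new.theta2 += np.where(land, flux_mm / mm2, 0.0)
        K2, _, _ = vg_hydraulics(np.clip(new.theta2, p.theta_r, p.theta_s), p)
        drain_mm = np.minimum(K2 * 1000.0 * dt, (new.theta2 - p.theta_r) * mm2)
        drain_mm = np.where(land, np.maximum(drain_mm, 0.0), 0.0)
        new.theta2 -= drain_mm / mm2
        drainage += drain_mm

    # (6) TWI redistribution within each basin (conserves each basin's total)
    if redistribute:
        for b in basins.basin_ids:
            bi, bj = basins.cells(b)
            if bi.size < 2:
                continue
            twi_b = basins.twi[bi, bj]
            w1 = new.theta1[bi, bj] * mm1
            new.theta1[bi, bj] = _twi_redistribute(
                w1, twi_b, p.theta_r * mm1, p.theta_s * mm1) / mm1
            w2 = new.theta2[bi, bj] * mm2
            new.theta2[bi, bj] = _twi_redistribute(
                w2, twi_b, p.theta_r * mm2, p.theta_s * mm2) / mm2

    # (7) pour-point overflow, highest pour elevation first
    export = 0.0
    for b in basins.processing_order():
        bi, bj = basins.cells(b)
        if bi.size == 0:
            continue
        over = np.maximum(new.surface_mm[bi, bj] - max_surface_mm, 0.0)
        surplus = float(over.sum())
        if surplus <= 0:
            continue
        new.surface_mm[bi, bj] -= over
        down = basins.downstream.get(b)
        if down is None or down not in basins.pour_point or basins.pour_point.get(down) is None:
            export += surplus
        else:
            pi, pj = basins.pour_point[down]
            new.surface_mm[pi, pj] += surplus

    storage_end = new.water_mm(land)
    budget = DayBudget(
        precip=float(precip[land].sum()),
        runoff=float(runoff[land].sum()),
        et_actual=float(et_actual[land].sum()),
        drainage=float(drainage[land].sum()),
        export=export,
        storage_start=storage_start,
        storage_end=storage_end,
    )
    return new, budget


def moisture_0_10cm(state: SoilColumnState) -> np.ndarray:
    """Thickness-weighted mean water content over the top 0.10 m."""
    depth = 0.10
    if state.d1 + state.d2 < depth:
        raise ValueError("soil column shallower than 0.10 m")
    w1 = min(state.d1, depth) / depth
    return w1 * state.theta1 + (1.0 - w1) * state.theta2


class SoilSimulation:
    """Run the daily soil model over a forcing series and keep the history."""

    def __init__(self, dem: RasterGrid, mask: LandSeaMask | None = None,
                 params: SoilHydraulicParams = LOAM, cn: float = 75.0,
                 bare_frac: float = 0.2, d1: float = 0.05, d2: float = 0.95,
                 theta_init: float | None = None):
        self.basins = delineate_basins(dem, mask)
        self.params = params
        self.cn = cn
        self.bare_frac = bare_frac
        land = self.basins.labels >= 0
        t0 = theta_init if theta_init is not None else 0.5 * (params.theta_r + params.theta_s)
        shape = dem.shape
        self.state = SoilColumnState(
            np.where(land, t0, np.nan), np.where(land, t0, np.nan), d1, d2)
        self.state.theta1 = np.nan_to_num(self.state.theta1, nan=t0)
        self.state.theta2 = np.nan_to_num(self.state.theta2, nan=t0)
        self.land = land
        self.shape = shape

    def run(self, precip: pd.DataFrame | pd.Series, pet: pd.Series,
            check_budget: bool = True) -> tuple[np.ndarray, pd.DataFrame]:
        """Step through days; returns (time, y, x) 0-10 cm moisture and the
        per-day budget table.  ``precip``/``pet`` are daily series (uniform
        over the grid) or DataFrames broadcastable to it."""
        recent = []
        rows = []
        frames = np.empty((len(pet), *self.shape), dtype=np.float32)
        for k, (day, pet_day) in enumerate(pet.items()):
            p_day = precip.loc[day]
            p_grid = np.full(self.shape, float(np.asarray(p_day).mean()))
            pet_grid = np.full(self.shape, float(pet_day))
            ante = float(np.sum(recent[-5:]))
            self.state, budget = step_soil_day(
                self.state, p_grid, pet_grid, self.basins, self.params,
                cn=self.cn, bare_frac=self.bare_frac, antecedent_5day_mm=ante)
            if check_budget and abs(budget.closure_error) > 1e-6 * max(self.land.sum(), 1):
                raise RuntimeError(
                    f"water budget failed to close on {day}: "
                    f"error {budget.closure_error:.3e} mm")
            recent.append(float(np.asarray(p_day).mean()))
            frames[k] = np.where(self.land, moisture_0_10cm(self.state), np.nan)
            rows.append({"date": day, **dataclasses.asdict(budget),
                         "closure_error": budget.closure_error})
        return frames, pd.DataFrame(rows).set_index("date")
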
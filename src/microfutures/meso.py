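"""Mesoclimate: land-sea temperature differentials and precipitation downscaling.

Hourly differences between land temperature and sea-surface temperature are
modelled with a thin-plate spline on terrain covariates — elevation, coastal
exposure in the upwind direction, and mean coastal exposure over all
directions — fitted at the coarse climate-grid scale and evaluated on the
fine grid with high-resolution versions of the same covariates.  Elevation
lapse, maritime buffering and (implicitly, through the spline surface)
cold-air pooling are captured this way without explicit drainage physics.

Precipitation is downscaled month by month: thin-plate splines of monthly
total and rain-day count on elevation are fitted at coarse scale, predicted
at fine scale, and each fine cell's daily series is the nearest coarse
cell's daily pattern rescaled to the predicted monthly total with wet days
toggled to match the predicted rain-day count.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .rasters import LandSeaMask, RasterGrid

__all__ = [
    "CoastalExposure",
    "TpsModel",
    "TpsResults",
    "coastal_exposure",
    "fit_mesoclimate_tps",
    "predict_mesoclimate_grid",
    "downscale_precipitation",
]


# ---------------------------------------------------------------------------
# Coastal exposure


@dataclasses.dataclass
class CoastalExposure:
    """Per-cell directional fraction of sea within a search radius.

    ``directional`` has shape (n_dir, ny, nx); directions are *from*-
    directions (degrees clockwise from north), matching the wind convention,
    so the exposure assigned to a westerly wind looks west.  ``mean`` is the
    all-direction average.  Values lie in [0, 1]: 1 for an all-sea
    neighbourhood, 0 for all-land.
    """

    directional: np.ndarray
    mean: np.ndarray
    directions: np.ndarray

    def upwind(self, winddir: float) -> np.ndarray:
        """Exposure in the sector nearest the wind's from-direction."""
        k = int(np.argmin(np.abs((self.directions - winddir + 180) % 360 - 180)))
        return self.directional[k]


def coastal_exposure(mask: LandSeaMask, radius_m: float = 10_000.0,
                     n_dir: int = 8) -> CoastalExposure:
    """Inverse-distance-weighted fraction of sea along rays in each direction.

    For every cell and direction a ray of sample points at one-cell steps is
    cast out to ``radius_m``; exposure is the 1/d-weighted fraction of
    samples that fall on sea.  Points beyond the raster edge continue the
    edge value (the domain boundary is assumed to continue its margin).
    """
    vals = mask.values
    if not np.isfinite(vals).any():
        raise ValueError("mask contains no data")
    ny, nx = mask.shape
    cell = mask.cell_size
    n_steps = int(radius_m // cell)
    if n_steps < 2:
        raise ValueError("search radius must cover at least 2 cells")
    sea = np.where(np.isfinite(vals), 1.0 - vals, 0.0)  # 1 where sea
    dirs = np.arange(n_dir) * 360.0 / n_dir
    ii, jj = np.mgrid[0:ny, 0:nx]
    directional = np.empty((n_dir, ny, nx))
    steps = np.arange(1, n_steps + 1)
    wts = 1.0 / steps
    for k, az in enumerate(dirs):
        azr = np.radians(az)
        di = -np.cos(azr)  # row displacement (north = -row)
        dj = np.sin(azr)
        acc = np.zeros((ny, nx))
        for s, w in zip(steps, wts):
            si = np.clip(np.rint(ii + di * s).astype(int), 0, ny - 1)
            sj = np.clip(np.rint(jj + dj * s).astype(int), 0, nx - 1)
            acc += w * sea[si, sj]
        directional[k] = acc / wts.sum()
    return CoastalExposure(directional=directional,
                           mean=directional.mean(axis=0),
                           directions=dirs)


# ---------------------------------------------------------------------------
# Thin-plate spline on terrain covariates


class TpsModel:
    """Thin-plate spline regression of a response on terrain covariates.

    Covariates are standardised internally; the spline carries a degree-1
    polynomial tail, so responses affine in the covariates are reproduced
    exactly at any smoothing.  The smoothing parameter is chosen by
    leave-one-out cross-validation over a log-spaced grid (a numerical
    stand-in for generalized cross-validation, exact at these sample sizes).
    """

    #: candidate smoothing values for LOO selection
    SMOOTHING_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)

    def __init__(self, covariates: np.ndarray, response: np.ndarray):
        X = np.asarray(covariates, dtype=float)
        y = np.asarray(response, dtype=float)
        if X.ndim != 2:
            raise ValueError("covariates must be (n, p)")
        n, p = X.shape
        if n < max(10, p + 2):
            raise ValueError(f"need at least {max(10, p + 2)} coarse cells, got {n}")
        self.X = X
        self.y = y
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        # constant or duplicated covariates make the spline's polynomial
        # block singular: keep one representative of each distinct column
        z = (X - self._mu) / self._sd
        active = []
        for k in range(p):
            if X[:, k].std() <= 1e-12 * (1.0 + np.abs(X[:, k]).max()):
                continue
            if any(np.allclose(z[:, k], z[:, a]) for a in active):
                continue
            active.append(k)
        if not active:
            active = [0]
        self._active = np.asarray(active)

    def _z(self, X: np.ndarray) -> np.ndarray:
        return ((X - self._mu) / self._sd)[:, self._active]

    def fit(self, smoothing: float | None = None) -> "TpsResults":
        Z = self._z(self.X)
        if smoothing is None:
            smoothing = self._select_smoothing(Z)
        interp = RBFInterpolator(Z, self.y, kernel="thin_plate_spline",
                                 smoothing=smoothing)
        fitted = interp(Z)
        resid = self.y - fitted
        return TpsResults(model=self, smoothing=float(smoothing), _interp=interp,
                          fitted=fitted, resid=resid,
                          ranges=np.stack([self.X.min(0), self.X.max(0)]))

    def _select_smoothing(self, Z: np.ndarray) -> float:
        n = Z.shape[0]
        best, best_err = 0.0, np.inf
        idx = np.arange(n)
        for s in self.SMOOTHING_GRID:
            errs = []
            for i in idx:
                keep = idx != i
                try:
                    f = RBFInterpolator(Z[keep], self.y[keep],
                                        kernel="thin_plate_spline", smoothing=s)
                except np.linalg.LinAlgError:
                    errs = None
                    break
                errs.append(float(f(Z[i:i + 1])[0] - self.y[i]))
            if errs is None:
                continue
            err = float(np.mean(np.square(errs)))
            if err < best_err - 1e-12:
                best, best_err = s, err
        return best


@dataclasses.dataclass
class TpsResults:
    model: TpsModel
    smoothing: float
    _interp: RBFInterpolator
    fitted: np.ndarray
    resid: np.ndarray
    ranges: np.ndarray  # (2, p): covariate min/max seen in training

    def predict(self, covariates: np.ndarray, warn_extrapolation: bool = True) -> np.ndarray:
        X = np.asarray(covariates, dtype=float)
        if warn_extrapolation:
            out = (X < self.ranges[0] - 1e-9) | (X > self.ranges[1] + 1e-9)
            if out.any():
                warnings.warn(
                    f"{int(out.any(axis=1).sum())} prediction points extrapolate "
                    "beyond the fitted covariate ranges", stacklevel=2)
        return self._interp(self.model._z(X))

    def summary(self) -> str:
        rmse = float(np.sqrt(np.mean(self.resid**2)))
        return (
            "Thin-plate spline fit\n"
            f"  n = {self.model.X.shape[0]}, covariates = {self.model.X.shape[1]}\n"
            f"  smoothing (LOO-selected) = {self.smoothing:g}\n"
            f"  training RMSE = {rmse:.4g}"
        )


def fit_mesoclimate_tps(
    land_temp: np.ndarray,
    sst: float,
    elevation: np.ndarray,
    exposure: CoastalExposure,
    winddir: float,
    coarse_land: np.ndarray | None = None,
) -> TpsResults:
    """Fit the land-sea differential spline for one hour.

    ``land_temp`` is the coarse-cell land temperature field for the hour,
    ``sst`` the sea-surface temperature; the response is their difference.
    Covariates are (elevation, upwind exposure for ``winddir``, mean
    exposure) at the same coarse cells.  ``coarse_land`` selects which cells
    enter the fit (default: all finite response cells).
    """
    up = exposure.upwind(winddir)
    resp = np.asarray(land_temp, dtype=float) - sst
    if coarse_land is None:
        coarse_land = np.isfinite(resp)
    sel = coarse_land & np.isfinite(resp)
    X = np.column_stack([
        np.asarray(elevation, dtype=float)[sel],
        up[sel],
        exposure.mean[sel],
    ])
    return TpsModel(X, resp[sel]).fit()


def predict_mesoclimate_grid(
    result: TpsResults,
    fine_elevation: RasterGrid,
    fine_exposure: CoastalExposure,
    winddir: float,
    sst: float,
    mask: LandSeaMask | None = None,
) -> RasterGrid:
    """Evaluate the fitted differential on the fine grid and add back SST.

    Sea cells (from ``mask``) are set to NaN.
    """
    elev = fine_elevation.values.astype(float)
    X = np.column_stack([
        elev.ravel(),
        fine_exposure.upwind(winddir).ravel(),
        fine_exposure.mean.ravel(),
    ])
    pred = sst + result.predict(X, warn_extrapolation=False).reshape(elev.shape)
    if mask is not None:
        pred = np.where(mask.land, pred, np.nan)
    return fine_elevation.copy_with(pred)


# ---------------------------------------------------------------------------
# Precipitation downscaling


def _monthly_tps_predict(coarse_elev: np.ndarray, values: np.ndarray,
                         fine_elev: np.ndarray) -> np.ndarray:
    """1-D thin-plate spline (elevation covariate) from coarse to fine."""
    X = np.asarray(coarse_elev, dtype=float).reshape(-1, 1)
    if np.ptp(X) == 0:
        return np.full(fine_elev.shape, float(np.mean(values)))
    if len(X) < 10:
        # too few cells for a spline: ordinary least squares on elevation
        b, a = np.polyfit(X.ravel(), np.asarray(values, dtype=float), 1)
        return a + b * fine_elev
    res = TpsModel(X, values).fit()
    return res.predict(fine_elev.reshape(-1, 1), warn_extrapolation=False).reshape(fine_elev.shape)


def downscale_precipitation(
    coarse_daily: pd.DataFrame,
    coarse_elev: np.ndarray,
    fine_elev: RasterGrid,
    coarse_xy: np.ndarray,
    wet_threshold: float = 0.2,
) -> "xr.DataArray":
    """Downscale daily precipitation from coarse cells to the fine grid.

    Parameters
    ----------
    coarse_daily
        DataFrame indexed by date with one column per coarse cell (mm/day).
    coarse_elev
        Elevation (m) of each coarse cell, aligned with the columns.
    fine_elev
        Fine-resolution DEM.
    coarse_xy
        (n_cells, 2) map coordinates of the coarse cell centres, used to
        assign each fine cell its nearest coarse daily pattern.
    wet_threshold
        Precipitation (mm) above which a day counts as a rain day.

    Month by month, splines of monthly total and rain-day count on elevation
    are fitted at coarse scale and predicted at fine scale.  The fine daily
    series is the nearest coarse cell's pattern rescaled to the predicted
    total; days are then toggled (driest wet days dried, or dry days given
    the sub-threshold trace) until the wet-day count matches the predicted
    count, re-conserving the monthly total at each step.  Negative predicted
    totals clip to zero with a warning.
    """
    import xarray as xr

    dates = pd.DatetimeIndex(coarse_daily.index)
    fe = np.nan_to_num(fine_elev.values.astype(float), nan=0.0)
    ny, nx = fe.shape
    fx, fy = fine_elev.cell_centers()
    # nearest coarse cell per fine cell
    d2 = ((fx.ravel()[:, None] - coarse_xy[:, 0]) ** 2
          + (fy.ravel()[:, None] - coarse_xy[:, 1]) ** 2)
    nearest = np.argmin(d2, axis=1).reshape(ny, nx)

    out = np.zeros((len(dates), ny, nx), dtype=np.float32)
    uniform = np.ptp(np.asarray(coarse_elev, dtype=float)) == 0
    for (yy, mm), sub in coarse_daily.groupby([dates.year, dates.month]):
        rows = np.nonzero((dates.year == yy) & (dates.month == mm))[0]
        totals = sub.sum(axis=0).to_numpy(dtype=float)
        raindays = (sub > wet_threshold).sum(axis=0).to_numpy(dtype=float)
        if uniform:
            # no elevation signal: every fine cell copies its nearest coarse cell
            for c in range(sub.shape[1]):
                ci, cj = np.nonzero(nearest == c)
                if ci.size:
                    out[rows[:, None], ci[None, :], cj[None, :]] = (
                        sub.iloc[:, c].to_numpy(dtype=np.float32)[:, None])
            continue
        tot_fine = _monthly_tps_predict(coarse_elev, totals, fe)
        if (tot_fine < 0).any():
            warnings.warn(f"negative predicted monthly totals in {yy}-{mm:02d} clipped to 0",
                          stacklevel=2)
            tot_fine = np.clip(tot_fine, 0.0, None)
        rd_fine = np.clip(np.rint(_monthly_tps_predict(coarse_elev, raindays, fe)),
                          0, len(rows)).astype(int)
        for c in range(sub.shape[1]):
            cells = np.nonzero(nearest == c)
            if cells[0].size == 0:
                continue
            pattern = sub.iloc[:, c].to_numpy(dtype=float)
            base_total = pattern.sum()
            for ci, cj in zip(*cells):
                target_total = float(tot_fine[ci, cj])
                series = (pattern * (target_total / base_total)
                          if base_total > 0 else np.zeros_like(pattern))
                series = _match_rainday_count(series, int(rd_fine[ci, cj]),
                                              target_total, wet_threshold)
                out[rows, ci, cj] = series.astype(np.float32)

    x1d = fx[0, :]
    y1d = fy[:, 0]
    return xr.DataArray(out, coords={"time": dates, "y": y1d, "x": x1d},
                        dims=("time", "y", "x"), name="precip")


def _match_rainday_count(series: np.ndarray, target_days: int, total: float,
                         wet_threshold: float) -> np.ndarray:
    """Toggle wet/dry days so the wet-day count matches, conserving the total."""
    s = series.copy()
    if total <= 0:
        return np.zeros_like(s)
    wet = s > wet_threshold
    n_wet = int(wet.sum())
    target_days = max(target_days, 1) if total > wet_threshold else target_days
    if n_wet > target_days:
        # dry the smallest wet days, moving their water to the wettest day
        order = np.argsort(np.where(wet, s, np.inf))
        imax = int(np.argmax(s))
        for i in order[: n_wet - target_days]:
            if i == imax:
                continue
            s[imax] += s[i]
            s[i] = 0.0
    elif n_wet < target_days:
        # promote the largest dry days using water from the wettest day
        dry_idx = np.argsort(np.where(wet, -np.inf, s))[::-1]
        imax = int(np.argmax(s))
        need = target_days - n_wet
        top_up = wet_threshold * 1.5
        for i in dry_idx[:need]:
            give = min(top_up, s[imax] * 0.5)
            if give <= wet_threshold:
                break
            s[imax] -= give
            s[i] += give
    return np.clip(s, 0.0, None)
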
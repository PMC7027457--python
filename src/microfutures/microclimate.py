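"""Near-surface temperature anomaly: the calibrated surface-coupling model.

The difference between near-surface (e.g. 5 cm) temperature and the 2-m
mesoclimate reference is treated as linear in net radiation, with a gradient
that measures how strongly the surface is thermally coupled to the
atmosphere.  Wind mixes the surface layer, so the gradient decays with wind
speed; here the decay is hyperbolic with one parameter:

    dT = c0 + c_base * Rnet / (1 + c_wind * u_z)

where ``Rnet`` is net radiation (W m-2) and ``u_z`` wind speed at sensor
height (m s-1).  ``c_base`` is the radiative coupling gradient at zero wind
(degC per W m-2), ``c_wind`` the wind-attenuation rate (s m-1) and ``c0`` a
small intercept; as u -> inf the anomaly collapses to c0 (full mixing).
Latent and soil heat fluxes are not modelled separately: they are assumed
small and proportional to net radiation, so they fold into ``c_base``.

The coefficients are fitted to field loggers by nonlinear least squares,
with calibration/validation splits that are independent in both space
(sites) and time (blocks).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rasters import LoggerSeries

__all__ = [
    "CouplingCoefficients",
    "CouplingModel",
    "CouplingResults",
    "predict_anomaly",
    "calibrate_coupling",
    "split_half",
]


@dataclasses.dataclass(frozen=True)
class CouplingCoefficients:
    """Surface-atmosphere thermal coupling parameters."""

    c_base: float  # degC per (W m-2) at zero wind
    c_wind: float  # s m-1, wind attenuation rate (>= 0)
    c0: float = 0.0  # degC intercept

    def as_array(self) -> np.ndarray:
        return np.array([self.c_base, self.c_wind, self.c0])


def predict_anomaly(rnet, u_z, coeff: CouplingCoefficients):
    """Temperature anomaly dT = c0 + c_base * rnet / (1 + c_wind * u_z)."""
    rnet = np.asarray(rnet, dtype=float)
    u_z = np.asarray(u_z, dtype=float)
    if (u_z < 0).any():
        raise ValueError("wind speed must be non-negative")
    return (coeff.c0 + coeff.c_base * rnet / (1.0 + coeff.c_wind * u_z))[()]


def split_half(n_sites: int, timestamps: pd.DatetimeIndex, seed: int = 0,
               n_time_blocks: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Half/half calibration-validation masks, independent in site AND time.

    Sites are split into two halves at random; timestamps are cut into
    ``n_time_blocks`` contiguous blocks, alternately assigned.  Calibration
    uses (site half A, block set A); validation uses (site half B, block set
    B) — doubly independent of the calibration data.  Returns boolean
    (site,) and (time,) masks: ``site_cal`` and ``time_cal``.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_sites)
    site_cal = np.zeros(n_sites, dtype=bool)
    site_cal[order[: max(1, n_sites // 2)]] = True
    edges = np.linspace(0, len(timestamps), n_time_blocks + 1).astype(int)
    time_cal = np.zeros(len(timestamps), dtype=bool)
    for b in range(n_time_blocks):
        if b % 2 == 0:
            time_cal[edges[b]:edges[b + 1]] = True
    return site_cal, time_cal


class CouplingModel:
    """Nonlinear least-squares calibration of the coupling coefficients.

    Parameters
    ----------
    loggers
        Field logger series (observed near-surface temperature).
    reference
        DataFrame of hourly mesoclimate reference temperature, one column
        per logger, indexed by timestamp.
    rnet
        Net radiation (W m-2) at each logger cell, same layout.
    u_z
        Wind speed at sensor height (m s-1), same layout.
    """

    #: fixed multi-start initial points (c_base, c_wind, c0)
    STARTS = (
        (0.01, 0.5, 0.0),
        (0.03, 2.0, 0.0),
        (0.001, 0.1, 0.0),
        (0.05, 5.0, 0.5),
        (-0.01, 1.0, 0.0),
    )

    def __init__(self, loggers: list[LoggerSeries], reference: pd.DataFrame,
                 rnet: pd.DataFrame, u_z: pd.DataFrame):
        if len(loggers) < 2:
            raise ValueError("need at least 2 loggers")
        self.loggers = loggers
        self.reference = reference
        self.rnet = rnet
        self.u_z = u_z
        idx = reference.index
        obs = pd.DataFrame(
            {c: lg.records.reindex(idx) for c, lg in zip(reference.columns, loggers)},
            index=idx)
        self.anomaly_obs = obs - reference
        n_pairs = int(self.anomaly_obs.notna().to_numpy().sum())
        if n_pairs < 100:
            raise ValueError(f"need >= 100 paired hours, got {n_pairs}")

    def _stack(self, site_mask: np.ndarray, time_mask: np.ndarray):
        cols = np.asarray(self.anomaly_obs.columns)[site_mask]
        sub = self.anomaly_obs.loc[time_mask, cols]
        r = self.rnet.loc[time_mask, cols].to_numpy().ravel()
        u = self.u_z.loc[time_mask, cols].to_numpy().ravel()
        y = sub.to_numpy().ravel()
        ok = np.isfinite(y) & np.isfinite(r) & np.isfinite(u)
        return r[ok], u[ok], y[ok]

    def fit(self, seed: int = 0, n_time_blocks: int = 8) -> "CouplingResults":
        site_cal, time_cal = split_half(len(self.loggers), self.anomaly_obs.index,
                                        seed=seed, n_time_blocks=n_time_blocks)
        r_cal, u_cal, y_cal = self._stack(site_cal, time_cal)
        r_val, u_val, y_val = self._stack(~site_cal, ~time_cal)

        def residuals(p):
            c_base, c_wind, c0 = p
            return c0 + c_base * r_cal / (1.0 + np.abs(c_wind) * u_cal) - y_cal

        best = None
        for start in self.STARTS:
            sol = least_squares(residuals, start, method="trf", max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success and best.cost > 1e6:
            gnorm = float(np.linalg.norm(best.grad)) if best is not None else np.nan
            raise RuntimeError(
                f"coupling calibration failed to converge (last iterate "
                f"{getattr(best, 'x', None)}, |grad| = {gnorm:.3g})")
        c_base, c_wind, c0 = best.x
        coeff = CouplingCoefficients(float(c_base), float(abs(c_wind)), float(c0))

        # parameter uncertainties from the Jacobian at the solution
        dof = max(r_cal.size - 3, 1)
        s2 = 2 * best.cost / dof
        J = best.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(3, np.nan)

        pred_cal = predict_anomaly(r_cal, u_cal, coeff)
        pred_val = predict_anomaly(r_val, u_val, coeff)
        return CouplingResults(
            model=self, coeff=coeff, bse=bse,
            n_cal=r_cal.size, n_val=r_val.size,
            rmse_cal=_rmse(pred_cal, y_cal), mae_cal=_mae(pred_cal, y_cal),
            rmse_val=_rmse(pred_val, y_val), mae_val=_mae(pred_val, y_val),
            site_cal=site_cal, time_cal=time_cal,
        )


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _mae(a, b) -> float:
    return float(np.mean(np.abs(np.asarray(a) - np.asarray(b))))


@dataclasses.dataclass
class CouplingResults:
    """Calibrated coupling coefficients with held-out validation metrics."""

    model: CouplingModel
    coeff: CouplingCoefficients
    bse: np.ndarray
    n_cal: int
    n_val: int
    rmse_cal: float
    mae_cal: float
    rmse_val: float
    mae_val: float
    site_cal: np.ndarray
    time_cal: np.ndarray

    def predict(self, rnet, u_z):
        return predict_anomaly(rnet, u_z, self.coeff)

    def summary(self) -> str:
        c = self.coeff
        rows = [
            ("c_base [degC/(W m-2)]", c.c_base, self.bse[0]),
            ("c_wind [s m-1]", c.c_wind, self.bse[1]),
            ("c0 [degC]", c.c0, self.bse[2]),
        ]
        lines = [
            "Surface coupling calibration",
            f"  n calibration = {self.n_cal}, n validation = {self.n_val}",
            f"  {'parameter':24s} {'estimate':>12s} {'std err':>10s}",
        ]
        for name, est, se in rows:
            lines.append(f"  {name:24s} {est:12.5g} {se:10.3g}")
        lines += [
            f"  calibration MAE/RMSE = {self.mae_cal:.3f} / {self.rmse_cal:.3f} degC",
            f"  validation  MAE/RMSE = {self.mae_val:.3f} / {self.rmse_val:.3f} degC",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "c_base": self.coeff.c_base, "c_wind": self.coeff.c_wind,
            "c0": self.coeff.c0,
            "bse": [float(v) for v in self.bse],
            "n_cal": self.n_cal, "n_val": self.n_val,
            "mae_val": self.mae_val, "rmse_val": self.rmse_val,
            "mae_cal": self.mae_cal, "rmse_cal": self.rmse_cal,
        }


def calibrate_coupling(loggers: list[LoggerSeries], reference: pd.DataFrame,
                       rnet: pd.DataFrame, u_z: pd.DataFrame,
                       seed: int = 0) -> CouplingResults:
    """Convenience wrapper: build a :class:`CouplingModel` and fit it."""
    return CouplingModel(loggers, reference, rnet, u_z).fit(seed=seed)
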
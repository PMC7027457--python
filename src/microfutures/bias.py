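"""Distribution-matching bias adjustment and daily-to-hourly disaggregation.

Climate-model runs carry systematic biases relative to observations at the
same location and period.  The adjustment here matches distributions: both
samples are ranked, a fixed number of paired order statistics is drawn at
equal probability intervals (with uniform jitter inside each interval), and
a monotone smooth is fitted through the pairs.  The fitted transform is then
applied to future runs, with linear extrapolation beyond the calibration
range using the slope of the terminal 5% of knots.

Daily weather is disaggregated to 24 UTC hours with a sine-shaped diurnal
temperature cycle (minimum at sunrise, maximum a fixed fraction of daylength
after sunrise, overnight relaxation toward the next morning's minimum),
clear-sky-weighted shortwave that conserves the daily total exactly, linear
noon-anchored interpolation of humidity and pressure, and constant-in-day
wind.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import ks_2samp

from . import radiation
from .rasters import HOURLY_COLUMNS

__all__ = [
    "QuantileMapModel",
    "QuantileMapResults",
    "build_quantile_map",
    "apply_quantile_map",
    "disaggregate_daily_to_hourly",
    "disaggregate_series",
]


# ---------------------------------------------------------------------------
# Quantile mapping


class QuantileMapModel:
    """Distribution-matching transform between a modelled and an observed sample.

    Parameters
    ----------
    observed, modelled
        Calibration-period samples of the same variable in the same units,
        each at least ``n_points`` long.
    variable
        Variable name; checked again when the transform is applied.
    n_points
        Number of paired order statistics used as knots (default 1200).
    """

    def __init__(self, observed, modelled, variable: str = "var", n_points: int = 1200):
        self.observed = np.asarray(observed, dtype=float)
        self.modelled = np.asarray(modelled, dtype=float)
        self.variable = variable
        self.n_points = int(n_points)
        if self.observed.size < self.n_points or self.modelled.size < self.n_points:
            raise ValueError(f"both samples must contain at least n_points={n_points} values")
        if np.ptp(self.modelled) == 0:
            raise ValueError("modelled sample is constant: transform undefined")

    def fit(self, seed: int | np.random.Generator = 0) -> "QuantileMapResults":
        """Pair order statistics at jittered equal-probability intervals and
        fit a monotone smooth through them."""
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        obs = np.sort(self.observed)
        mod = np.sort(self.modelled)
        n = self.n_points
        # n equal probability intervals, one uniformly jittered draw in each
        probs = (np.arange(n) + rng.uniform(size=n)) / n
        x = np.quantile(mod, probs)  # modelled scale
        y = np.quantile(obs, probs)  # observed scale
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        y = _monotone_pava(y)
        # collapse ties in x so the interpolant is well defined
        xs, inv = np.unique(x, return_inverse=True)
        ys = np.zeros_like(xs)
        np.add.at(ys, inv, y)
        ys /= np.bincount(inv)
        transform = PchipInterpolator(xs, ys, extrapolate=False)
        # terminal slopes from the outer 5% of knots for linear extrapolation
        k = max(2, int(0.05 * xs.size))
        lo_slope = _slope(xs[:k], ys[:k])
        hi_slope = _slope(xs[-k:], ys[-k:])
        ks_before = float(ks_2samp(self.observed, self.modelled).statistic)
        res = QuantileMapResults(
            model=self, knots_x=xs, knots_y=ys, _interp=transform,
            lo_slope=lo_slope, hi_slope=hi_slope, ks_before=ks_before, ks_after=np.nan,
        )
        res.ks_after = float(ks_2samp(self.observed, res.apply(self.modelled)).statistic)
        return res


def _monotone_pava(y: np.ndarray) -> np.ndarray:
    """Project a sequence onto the non-decreasing cone (pool adjacent violators)."""
    y = y.astype(float).copy()
    n = y.size
    w = np.ones(n)
    # classic PAVA with merged blocks
    vals: list[float] = []
    wts: list[float] = []
    idx: list[int] = []
    for i in range(n):
        vals.append(y[i]); wts.append(w[i]); idx.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]; idx[-2] += idx[-1]
            vals[-2] = v
            vals.pop(); wts.pop(); idx.pop()
    out = np.empty(n)
    pos = 0
    for v, c in zip(vals, idx):
        out[pos:pos + c] = v
        pos += c
    return out


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 1.0
    b = np.polyfit(x, y, 1)[0]
    return float(max(b, 0.0))


@dataclasses.dataclass
class QuantileMapResults:
    """A fitted monotone quantile-mapping transform with its diagnostics."""

    model: QuantileMapModel
    knots_x: np.ndarray
    knots_y: np.ndarray
    _interp: PchipInterpolator
    lo_slope: float
    hi_slope: float
    ks_before: float
    ks_after: float

    @property
    def variable(self) -> str:
        return self.model.variable

    def apply(self, values, variable: str | None = None) -> np.ndarray:
        """Map modelled-scale values to the observed scale.

        Inside the knot range the monotone smooth applies; outside it the
        transform continues linearly with the terminal slopes, so the order
        of inputs is always preserved.
        """
        if variable is not None and variable != self.variable:
            raise ValueError(f"transform is for {self.variable!r}, not {variable!r}")
        v = np.asarray(values, dtype=float)
        out = self._interp(v)
        xlo, xhi = self.knots_x[0], self.knots_x[-1]
        ylo, yhi = self.knots_y[0], self.knots_y[-1]
        below = v < xlo
        above = v > xhi
        out = np.where(below, ylo + self.lo_slope * (v - xlo), out)
        out = np.where(above, yhi + self.hi_slope * (v - xhi), out)
        return out

    def __call__(self, values) -> np.ndarray:
        return self.apply(values)

    def summary(self) -> str:
        lines = [
            f"Quantile map for {self.variable!r}",
            f"  knots: {self.knots_x.size} (requested {self.model.n_points})",
            f"  range (modelled): [{self.knots_x[0]:.4g}, {self.knots_x[-1]:.4g}]",
            f"  terminal slopes: lo={self.lo_slope:.4g}, hi={self.hi_slope:.4g}",
            f"  KS distance before: {self.ks_before:.4f}",
            f"  KS distance after:  {self.ks_after:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_knots": int(self.knots_x.size),
            "ks_before": self.ks_before,
            "ks_after": self.ks_after,
            "lo_slope": self.lo_slope,
            "hi_slope": self.hi_slope,
        }


def build_quantile_map(observed, modelled, variable: str = "var",
                       n_points: int = 1200, seed: int = 0) -> QuantileMapResults:
    """Convenience wrapper: construct and fit a :class:`QuantileMapModel`."""
    return QuantileMapModel(observed, modelled, variable, n_points).fit(seed)


def apply_quantile_map(qmap: QuantileMapResults, values, variable: str | None = None) -> np.ndarray:
    return qmap.apply(values, variable)


# ---------------------------------------------------------------------------
# Daily -> hourly disaggregation


def _diurnal_shape(hours: np.ndarray, sunrise: float, sunset: float,
                   peak_frac: float = 0.55, night_tau: float = 3.5) -> np.ndarray:
    """Dimensionless diurnal temperature shape in [0, 1].

    Sine limb rising from the sunrise minimum to a maximum ``peak_frac`` of
    the daylength after sunrise, then a falling sine limb until sunset and
    an exponential decay overnight toward the next sunrise minimum.
    """
    daylen = sunset - sunrise
    t_peak = sunrise + peak_frac * daylen
    s = np.empty_like(hours, dtype=float)
    h = hours
    rising = (h >= sunrise) & (h <= t_peak)
    s[rising] = 0.5 * (1 - np.cos(np.pi * (h[rising] - sunrise) / (t_peak - sunrise)))
    falling = (h > t_peak) & (h <= sunset)
    # decay from the peak toward the sunset value along a quarter sine
    s[falling] = np.cos(0.5 * np.pi * (h[falling] - t_peak) / (sunset - t_peak)) ** 0.7
    night = ~(rising | falling)
    hn = h[night].copy()
    hn = np.where(hn < sunrise, hn + 24.0, hn)  # hours since previous sunset
    s_sunset = np.cos(0.5 * np.pi) ** 0.7 if sunset > t_peak else 1.0
    s_sunset = max(s_sunset, 1e-3)
    elapsed = hn - sunset
    night_len = 24.0 - daylen
    s[night] = s_sunset * np.exp(-elapsed / night_tau) * (1 - elapsed / night_len) ** 0.2
    return np.clip(s, 0.0, 1.0)


def disaggregate_daily_to_hourly(
    day: pd.Series,
    lat: float,
    lon: float,
    day_before: pd.Series | None = None,
    day_after: pd.Series | None = None,
    date: dt.date | None = None,
    peak_frac: float = 0.55,
    winddir: float = 225.0,
) -> pd.DataFrame:
    """Expand one daily weather record into 24 hourly records (UTC).

    The hourly temperatures are affinely rescaled so their min and max hit
    tmin and tmax exactly; shortwave is distributed over hours proportional
    to the clear-sky flux and converted so the daily sum reproduces the
    MJ m-2 day-1 total exactly; humidity and pressure interpolate linearly
    between the neighbouring days' noon-anchored values; wind speed is
    constant within the day.
    """
    if date is None:
        date = day.name if isinstance(day.name, (dt.date, pd.Timestamp)) else dt.date(2000, 6, 21)
    if isinstance(date, pd.Timestamp):
        date = date.date()
    day_before = day if day_before is None else day_before
    day_after = day if day_after is None else day_after

    hours = np.arange(24, dtype=float) + 0.5
    times = pd.date_range(
        dt.datetime(date.year, date.month, date.day, 0, 30, tzinfo=dt.timezone.utc),
        periods=24, freq="h",
    )
    sunrise, sunset = radiation.sunrise_sunset_hours(
        lat, lon, dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc))
    if not (0 < sunset - sunrise < 24):
        raise ValueError("degenerate daylength outside supported latitudes")

    shape = _diurnal_shape(hours, sunrise, sunset, peak_frac)
    smin, smax = shape.min(), shape.max()
    if smax > smin:
        shape = (shape - smin) / (smax - smin)
    else:
        shape = np.zeros_like(shape)
    temp = day["tmin"] + (day["tmax"] - day["tmin"]) * shape

    # shortwave: clear-sky weights, exact conservation of the daily total
    cs = np.array([
        radiation.clear_sky_radiation(lat, lon, t.to_pydatetime()) for t in times
    ])
    total_wm2h = day["swdown"] * 1e6 / 3600.0  # MJ m-2 day-1 -> (W m-2) x hours
    wsum = cs.sum()
    swrad = cs / wsum * total_wm2h if wsum > 0 else np.zeros(24)

    # humidity / pressure: linear between noon-anchored daily values
    frac = (hours - 12.0) / 24.0
    def interp(col: str) -> np.ndarray:
        prev_v, cur_v, next_v = day_before[col], day[col], day_after[col]
        out = np.where(frac < 0, cur_v + (-frac) * (prev_v - cur_v),
                       cur_v + frac * (next_v - cur_v))
        return out
    shum = interp("shum")
    pres = interp("pres")

    return pd.DataFrame(
        {
            "temp": temp,
            "swrad": swrad,
            "shum": shum,
            "pres": pres,
            "wind": np.full(24, float(day["wind"])),
            "winddir": np.full(24, float(winddir)),
        },
        index=times,
    )[list(HOURLY_COLUMNS)]


def disaggregate_series(daily: pd.DataFrame, lat: float, lon: float,
                        seed: int = 0,
                        winddir_climatology: np.ndarray | None = None) -> pd.DataFrame:
    """Disaggregate a full daily table to hourly, day by day.

    Wind direction is drawn per day from ``winddir_climatology`` (a sample of
    from-directions in degrees; default a south-westerly maritime regime).
    """
    rng = np.random.default_rng(seed)
    if winddir_climatology is None:
        winddir_climatology = np.array([180.0, 202.5, 225.0, 225.0, 247.5, 270.0, 315.0, 135.0])
    rows = []
    dates = list(daily.index)
    for k, d in enumerate(dates):
        prev_row = daily.iloc[max(k - 1, 0)]
        next_row = daily.iloc[min(k + 1, len(dates) - 1)]
        wd = float(rng.choice(winddir_climatology))
        rows.append(disaggregate_daily_to_hourly(
            daily.loc[d], lat, lon, prev_row, next_row, date=d, winddir=wd))
    return pd.concat(rows)
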
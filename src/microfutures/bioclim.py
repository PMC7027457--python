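"""Bioclimate summary variables, decadal trends and the climate-novelty index.

The 19 Worldclim BIO variables are computed from a calendar year of hourly
temperature and daily precipitation; the 11 PHYS variables add the
physiologically relevant summaries (frost hours, growing-season means,
waterlogged/drought spells, growing degree-hours) that need hourly and
soil-moisture input.  "Quarters" follow the Worldclim convention: all twelve
contiguous three-month windows, wrapping across the year end, with the
extreme window selected per variable.

Decadal trends are ordinary least-squares slopes on annual values times ten.
Novelty compares the frequency distribution of annual values in a historic
period with that of all pooled future runs: one minus the histogram overlap,
0 for identical distributions, 1 for disjoint ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .soil import SoilHydraulicParams, LOAM, wilting_point

__all__ = [
    "compute_bio",
    "growing_season_mask",
    "compute_phys",
    "compute_all",
    "decadal_trend",
    "novelty_index",
    "BIO_NAMES",
    "PHYS_NAMES",
]

BIO_NAMES = tuple(f"BIO{i}" for i in range(1, 20))
PHYS_NAMES = tuple(f"PHYS{i}" for i in range(1, 12))


def _monthly_frames(hourly_temp: pd.Series, daily_precip: pd.Series):
    t = hourly_temp
    if t.index.tz is not None:
        t = pd.Series(t.to_numpy(), index=t.index.tz_localize(None))
    months_present = sorted(set(t.index.month))
    if months_present != list(range(1, 13)):
        raise ValueError("hourly temperature must cover a full calendar year")
    daily = t.resample("D")
    dmax = daily.max()
    dmin = daily.min()
    dmean = daily.mean()
    by_month = dmean.groupby(dmean.index.month)
    tmean_m = by_month.mean()
    tmax_m = dmax.groupby(dmax.index.month).mean()   # monthly mean daily max
    tmin_m = dmin.groupby(dmin.index.month).mean()
    p = daily_precip
    p = pd.Series(np.asarray(p, dtype=float), index=pd.DatetimeIndex(p.index))
    prec_m = p.groupby(p.index.month).sum()
    if len(prec_m) != 12:
        raise ValueError("daily precipitation must cover a full calendar year")
    month_days = p.groupby(p.index.month).size()
    return tmean_m, tmax_m, tmin_m, prec_m, month_days


def _quarters(values: pd.Series) -> np.ndarray:
    """Sums/means over all 12 wrapped 3-month windows: row k = months k..k+2."""
    v = values.reindex(range(1, 13)).to_numpy()
    vv = np.concatenate([v, v[:2]])
    return np.stack([vv[k:k + 3] for k in range(12)])


def compute_bio(hourly_temp: pd.Series, daily_precip: pd.Series) -> dict[str, float]:
    """The 19 Worldclim bioclim variables for one calendar year.

    ``hourly_temp`` (degC) and ``daily_precip`` (mm/day) must each span the
    full year.  BIO5/BIO6 use the hottest/coldest month's mean daily
    extremes; BIO4 is the SD of monthly means x 100; BIO3 = BIO2/BIO7 x 100.
    """
    tmean_m, tmax_m, tmin_m, prec_m, month_days = _monthly_frames(hourly_temp, daily_precip)
    q_t = _quarters(tmean_m).mean(axis=1)
    q_p = _quarters(prec_m).sum(axis=1)

    bio: dict[str, float] = {}
    bio["BIO1"] = float(tmean_m.mean())
    diurnal = (tmax_m - tmin_m)
    bio["BIO2"] = float(diurnal.mean())
    bio["BIO5"] = float(tmax_m.max())
    bio["BIO6"] = float(tmin_m.min())
    bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
    bio["BIO3"] = (bio["BIO2"] / bio["BIO7"] * 100.0) if bio["BIO7"] != 0 else 0.0
    bio["BIO4"] = float(tmean_m.std(ddof=0) * 100.0)
    wettest_q = int(np.argmax(q_p))
    driest_q = int(np.argmin(q_p))
    warmest_q = int(np.argmax(q_t))
    coldest_q = int(np.argmin(q_t))
    bio["BIO8"] = float(q_t[wettest_q])
    bio["BIO9"] = float(q_t[driest_q])
    bio["BIO10"] = float(q_t[warmest_q])
    bio["BIO11"] = float(q_t[coldest_q])
    bio["BIO12"] = float(prec_m.sum())
    bio["BIO13"] = float(prec_m.max())
    bio["BIO14"] = float(prec_m.min())
    # seasonality as CV of monthly *daily-mean* rates so unequal month
    # lengths do not register as seasonality
    p_rate = prec_m / month_days.reindex(prec_m.index).to_numpy()
    mean_p = p_rate.mean()
    bio["BIO15"] = float(p_rate.std(ddof=0) / mean_p * 100.0) if mean_p > 0 else 0.0
    bio["BIO16"] = float(q_p[wettest_q])
    bio["BIO17"] = float(q_p[driest_q])
    bio["BIO18"] = float(q_p[warmest_q])
    bio["BIO19"] = float(q_p[coldest_q])
    return bio


def growing_season_mask(daily_temp: pd.Series, daily_precip: pd.Series,
                        daily_pet: pd.Series) -> pd.Series:
    """Days in the growing season: centred 5-day means of precipitation must
    exceed half the potential evapotranspiration while 5-day mean temperature
    lies between 5 and 35 degC (window truncated at the series edges)."""
    roll = dict(window=5, center=True, min_periods=1)
    p5 = daily_precip.rolling(**roll).mean()
    e5 = daily_pet.rolling(**roll).mean()
    t5 = daily_temp.rolling(**roll).mean()
    return (p5 > 0.5 * e5) & (t5 >= 5.0) & (t5 <= 35.0)


def _longest_run(cond: np.ndarray) -> int:
    best = cur = 0
    for c in cond:
        cur = cur + 1 if c else 0
        best = max(best, cur)
    return best


def compute_phys(hourly_temp: pd.Series, daily_precip: pd.Series,
                 daily_soil_moisture: pd.Series, season_mask: pd.Series,
                 params: SoilHydraulicParams = LOAM,
                 waterlog_margin: float = 0.01,
                 gdh_base: float = 5.0) -> dict[str, float]:
    """The 11 physiological variables for one calendar year.

    Frost hours count hourly temperatures below 0 degC; the frost-free
    season is the longest run of days with no sub-zero hour; waterlogged
    days have moisture within ``waterlog_margin`` of saturation; drought
    days sit at or below the wilting-point content (retention curve at
    -150 m matric potential); growing degree-hours accumulate
    max(0, T - base)/1000 over the year.
    """
    t = hourly_temp
    if t.index.tz is not None:
        t = pd.Series(t.to_numpy(), index=t.index.tz_localize(None))
    sm = daily_soil_moisture
    season = season_mask.to_numpy(dtype=bool)

    phys: dict[str, float] = {}
    phys["PHYS1"] = float(sm.to_numpy()[season].mean()) if season.any() else np.nan
    daily_mean_t = t.resample("D").mean()
    phys["PHYS2"] = float(daily_mean_t.to_numpy()[season].mean()) if season.any() else np.nan
    phys["PHYS3"] = float(daily_precip.to_numpy()[season].sum())
    phys["PHYS4"] = int(season.sum())
    summer = sm.index.month.isin((6, 7, 8))
    phys["PHYS5"] = float(sm.to_numpy()[summer].mean())
    phys["PHYS6"] = int((t < 0.0).sum())
    frost_day = (t < 0.0).resample("D").max().astype(bool)
    phys["PHYS7"] = _longest_run(~frost_day.to_numpy())
    phys["PHYS8"] = int((t > 25.0).sum())
    phys["PHYS9"] = _longest_run(sm.to_numpy() >= params.theta_s - waterlog_margin)
    phys["PHYS10"] = _longest_run(sm.to_numpy() <= wilting_point(params))
    phys["PHYS11"] = float(np.maximum(t.to_numpy() - gdh_base, 0.0).sum() / 1000.0)
    return phys


def compute_all(hourly_temp: pd.Series, daily_precip: pd.Series,
                daily_soil_moisture: pd.Series, daily_pet: pd.Series,
                params: SoilHydraulicParams = LOAM) -> dict[str, float]:
    """All 30 variables (BIO1-19 then PHYS1-11) for one cell-year."""
    t = hourly_temp
    tt = pd.Series(t.to_numpy(), index=t.index.tz_localize(None)) if t.index.tz is not None else t
    daily_temp = tt.resample("D").mean()
    season = growing_season_mask(daily_temp, daily_precip, daily_pet)
    out = compute_bio(hourly_temp, daily_precip)
    out.update(compute_phys(hourly_temp, daily_precip, daily_soil_moisture,
                            season, params))
    return out


def decadal_trend(annual_values: pd.Series | np.ndarray,
                  years: np.ndarray | None = None) -> float:
    """Change per decade: OLS slope of annual values on year, times ten."""
    if isinstance(annual_values, pd.Series):
        years = np.asarray(annual_values.index, dtype=float)
        vals = annual_values.to_numpy(dtype=float)
    else:
        vals = np.asarray(annual_values, dtype=float)
        if years is None:
            years = np.arange(len(vals), dtype=float)
        years = np.asarray(years, dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 annual values for a trend")
    slope = np.polyfit(years, vals, 1)[0]
    return float(slope * 10.0)


def novelty_index(historic_annual, future_annual_all_runs,
                  n_bins: int | None = None) -> float:
    """1 minus the overlap of the two frequency distributions, in [0, 1].

    Both samples are binned on one common grid spanning their union (bin
    width by Freedman-Diaconis on the pooled sample unless ``n_bins`` is
    given); overlap is the sum of per-bin minima of the two normalised
    histograms.  Identical samples give 0; disjoint supports give 1.  The
    index is symmetric and invariant to a joint affine rescaling.
    """
    a = np.asarray(historic_annual, dtype=float)
    b = np.asarray(future_annual_all_runs, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 values in each sample")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return 0.0
    if n_bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
        n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else 10
        n_bins = int(np.clip(n_bins, 4, 200))
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    overlap = np.minimum(pa / a.size, pb / b.size).sum()
    return float(1.0 - overlap)
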
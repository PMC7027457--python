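"""Bioclim and physiological variables, trends and the novelty index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microfutures import bioclim
from microfutures.soil import LOAM, wilting_point


def hourly_year(values, year=2001):
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    return pd.Series(np.broadcast_to(values, len(idx)).copy(), index=idx)


def daily_year(values, year=2001):
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return pd.Series(np.broadcast_to(values, len(idx)).copy(), index=idx)


@pytest.fixture(scope="module")
def random_year():
    rng = np.random.default_rng(12)
    idx = pd.date_range("2001-01-01", "2001-12-31 23:00", freq="h")
    doy = idx.dayofyear.to_numpy()
    temp = 10 - 7 * np.cos(2 * np.pi * doy / 365) \
        + 4 * np.sin(2 * np.pi * idx.hour.to_numpy() / 24) \
        + rng.normal(0, 1.5, len(idx))
    precip = daily_year(0.0)
    precip[:] = rng.gamma(0.6, 5, len(precip)) * (rng.uniform(size=len(precip)) < 0.4)
    return pd.Series(temp, index=idx), precip


class TestBio:
    def test_constant_climate_forces_degenerate_values(self):
        bio = bioclim.compute_bio(hourly_year(10.0), daily_year(2.0))
        assert bio["BIO1"] == pytest.approx(10.0)
        assert bio["BIO4"] == pytest.approx(0.0)
        assert bio["BIO7"] == pytest.approx(0.0)
        assert bio["BIO15"] == pytest.approx(0.0, abs=1e-9)
        assert bio["BIO12"] == pytest.approx(2.0 * 365)

    def test_table_identities_on_random_year(self, random_year):
        temp, precip = random_year
        bio = bioclim.compute_bio(temp, precip)
        assert bio["BIO7"] == pytest.approx(bio["BIO5"] - bio["BIO6"], abs=1e-12)
        assert bio["BIO3"] == pytest.approx(bio["BIO2"] / bio["BIO7"] * 100, abs=1e-9)
        assert bio["BIO5"] >= bio["BIO6"]
        assert bio["BIO13"] >= bio["BIO14"]
        for k in ("BIO12", "BIO13", "BIO14", "BIO16", "BIO17", "BIO18", "BIO19"):
            assert bio[k] >= 0
        # quarter extremes bound the mean
        assert bio["BIO10"] >= bio["BIO1"] >= bio["BIO11"]

    def test_seasonality_of_sampled_sinusoid(self):
        # monthly means ~ A cos(month angle): population SD = A/sqrt(2)
        idx = pd.date_range("2001-01-01", "2001-12-31 23:00", freq="h")
        month_mid = (idx.month.to_numpy() - 0.5) / 12
        A = 8.0
        temp = pd.Series(10 + A * np.cos(2 * np.pi * month_mid), index=idx)
        bio = bioclim.compute_bio(temp, daily_year(1.0))
        assert bio["BIO4"] == pytest.approx(100 * A / np.sqrt(2), rel=0.02)

    def test_partial_year_rejected(self):
        idx = pd.date_range("2001-01-01", "2001-06-30 23:00", freq="h")
        with pytest.raises(ValueError, match="calendar year"):
            bioclim.compute_bio(pd.Series(10.0, index=idx), daily_year(1.0))


class TestGrowingSeason:
    def test_cold_year_has_empty_season(self):
        m = bioclim.growing_season_mask(daily_year(0.0), daily_year(10.0),
                                        daily_year(4.0))
        assert m.sum() == 0

    def test_benign_year_is_all_season(self):
        m = bioclim.growing_season_mask(daily_year(15.0), daily_year(10.0),
                                        daily_year(4.0))
        assert m.all()

    def test_qualifying_block_matches_bruteforce(self):
        temp = daily_year(0.0)
        precip = daily_year(0.0)
        pet = daily_year(4.0)
        temp.iloc[120:160] = 15.0
        precip.iloc[120:160] = 10.0
        m = bioclim.growing_season_mask(temp, precip, pet)

        # brute-force day-by-day evaluation with truncated windows
        t, p, e = temp.to_numpy(), precip.to_numpy(), pet.to_numpy()
        n = len(t)
        expect = np.zeros(n, dtype=bool)
        for k in range(n):
            lo, hi = max(0, k - 2), min(n, k + 3)
            p5, e5, t5 = p[lo:hi].mean(), e[lo:hi].mean(), t[lo:hi].mean()
            expect[k] = (p5 > 0.5 * e5) and (5 <= t5 <= 35)
        np.testing.assert_array_equal(m.to_numpy(), expect)


class TestPhys:
    def _inputs(self, temp_series):
        precip = daily_year(3.0)
        sm = daily_year(0.25)
        season = pd.Series(True, index=precip.index)
        return temp_series, precip, sm, season

    def test_mild_year_has_no_frost_or_heat(self):
        t, p, sm, season = self._inputs(hourly_year(10.0))
        phys = bioclim.compute_phys(t, p, sm, season)
        assert phys["PHYS6"] == 0
        assert phys["PHYS8"] == 0
        assert phys["PHYS7"] == 365

    def test_one_freezing_week_counts_168_hours(self):
        temp = hourly_year(10.0)
        temp.iloc[24 * 100:24 * 107] = -1.0
        t, p, sm, season = self._inputs(temp)
        phys = bioclim.compute_phys(t, p, sm, season)
        assert phys["PHYS6"] == 168
        assert phys["PHYS7"] == 365 - 107  # longest frost-free run after the week

    def test_degree_hours_arithmetic(self):
        t, p, sm, season = self._inputs(hourly_year(15.0))
        phys = bioclim.compute_phys(t, p, sm, season, gdh_base=5.0)
        assert phys["PHYS11"] == pytest.approx(10.0 * 8760 / 1000.0)

    def test_waterlog_and_wilting_runs(self):
        t, p, sm, season = self._inputs(hourly_year(12.0))
        sm.iloc[50:60] = LOAM.theta_s  # 10 waterlogged days
        sm.iloc[200:230] = wilting_point(LOAM) - 0.001  # 30 drought days
        phys = bioclim.compute_phys(t, p, sm, season, params=LOAM)
        assert phys["PHYS9"] == 10
        assert phys["PHYS10"] == 30


class TestTrend:
    def test_constant_series_has_zero_trend(self):
        s = pd.Series(5.0, index=range(1983, 2018))
        assert bioclim.decadal_trend(s) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_line_exact(self):
        years = np.arange(1983, 2018)
        s = pd.Series(0.07 * years - 100.0, index=years)
        assert bioclim.decadal_trend(s) == pytest.approx(0.7, abs=1e-9)

    def test_noisy_line_within_three_standard_errors(self):
        rng = np.random.default_rng(21)
        years = np.arange(1983, 2018)
        sigma = 0.4
        s = pd.Series(0.05 * years + rng.normal(0, sigma, len(years)), index=years)
        est = bioclim.decadal_trend(s)
        xc = years - years.mean()
        se_slope = sigma / np.sqrt((xc**2).sum())
        assert abs(est - 0.5) <= 3 * se_slope * 10

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bioclim.decadal_trend(pd.Series([1.0, 2.0], index=[2000, 2001]))


class TestNovelty:
    def test_identical_samples_give_zero(self):
        x = np.random.default_rng(0).normal(0, 1, 500)
        assert bioclim.novelty_index(x, x.copy()) == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        a = np.linspace(0, 1, 100)
        b = np.linspace(10, 11, 100)
        assert bioclim.novelty_index(a, b) == pytest.approx(1.0)

    def test_half_overlapping_uniforms(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0.0, 2.0, 200_000)
        b = rng.uniform(1.0, 3.0, 200_000)
        # uniforms sharing half their width: overlap 0.5, novelty 0.5
        assert bioclim.novelty_index(a, b, n_bins=40) == pytest.approx(0.5, abs=0.03)

    def test_symmetric_in_samples(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 400)
        b = rng.normal(1, 1.5, 400)
        assert bioclim.novelty_index(a, b) == pytest.approx(
            bioclim.novelty_index(b, a), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    def test_invariant_to_joint_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 300)
        b = rng.normal(0.8, 1.2, 300)
        base = bioclim.novelty_index(a, b)
        moved = bioclim.novelty_index(a * scale + shift, b * scale + shift)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            bioclim.novelty_index([1.0, 2.0], [3.0, 4.0, 5.0, 6.0, 7.0])
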
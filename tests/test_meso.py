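"""Coastal exposure, the mesoclimate spline and precipitation downscaling."""

import numpy as np
import pandas as pd
import pytest

from microfutures import meso
from microfutures.rasters import LandSeaMask, RasterGrid


def make_mask(values, cell=100.0):
    values = np.asarray(values, dtype=np.float32)
    return LandSeaMask(values, 0.0, values.shape[0] * cell, cell)


def exposure_ray_oracle(sea, i, j, az_deg, n_steps):
    """Naive per-cell ray walk: inverse-distance-weighted sea fraction."""
    ny, nx = sea.shape
    azr = np.radians(az_deg)
    num = den = 0.0
    for s in range(1, n_steps + 1):
        si = int(np.rint(i - np.cos(azr) * s))
        sj = int(np.rint(j + np.sin(azr) * s))
        si = min(max(si, 0), ny - 1)
        sj = min(max(sj, 0), nx - 1)
        w = 1.0 / s
        num += w * sea[si, sj]
        den += w
    return num / den


class TestCoastalExposure:
    def test_all_land_is_zero(self):
        ce = meso.coastal_exposure(make_mask(np.ones((16, 16))), 800.0, 8)
        np.testing.assert_allclose(ce.directional, 0.0)
        np.testing.assert_allclose(ce.mean, 0.0)

    def test_all_sea_is_one(self):
        ce = meso.coastal_exposure(make_mask(np.zeros((16, 16))), 800.0, 8)
        np.testing.assert_allclose(ce.directional, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        vals = (rng.uniform(size=(32, 32)) > 0.45).astype(np.float32)
        mask = make_mask(vals)
        radius, n_dir = 900.0, 8
        ce = meso.coastal_exposure(mask, radius, n_dir)
        sea = (1.0 - vals).astype(np.float64)
        n_steps = int(radius // mask.cell_size)
        for i, j in [(5, 7), (16, 16), (30, 2), (0, 31)]:
            for k, az in enumerate(ce.directions):
                oracle = exposure_ray_oracle(sea, i, j, az, n_steps)
                assert ce.directional[k, i, j] == pytest.approx(oracle, abs=1e-12)

    def test_half_plane_east(self):
        vals = np.ones((16, 16), dtype=np.float32)
        vals[:, 8:] = 0.0  # sea to the east
        ce = meso.coastal_exposure(make_mask(vals), 700.0, 8)
        east = ce.directional[2]  # 90 degrees
        west = ce.directional[6]  # 270 degrees
        assert east[8, 4] > 0.0
        assert west[8, 4] == 0.0

    def test_too_small_radius_rejected(self):
        with pytest.raises(ValueError):
            meso.coastal_exposure(make_mask(np.ones((8, 8))), 50.0, 8)


class TestTpsModel:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.elev = rng.uniform(0.0, 250.0, 16)
        self.up = rng.uniform(0.0, 1.0, 16)
        self.mean = rng.uniform(0.0, 1.0, 16)
        self.X = np.column_stack([self.elev, self.up, self.mean])

    def test_zero_response_predicts_zero(self):
        res = meso.TpsModel(self.X, np.zeros(16)).fit()
        fine = np.column_stack([np.linspace(0, 250, 200),
                                np.full(200, 0.4), np.full(200, 0.6)])
        np.testing.assert_allclose(res.predict(fine, warn_extrapolation=False),
                                   0.0, atol=1e-10)

    def test_elevation_lapse_recovered(self):
        resp = -0.006 * self.elev
        res = meso.TpsModel(self.X, resp).fit()
        fine_elev = np.linspace(0, 250, 500)
        fine = np.column_stack([fine_elev, np.full(500, 0.5), np.full(500, 0.5)])
        pred = res.predict(fine, warn_extrapolation=False)
        truth = -0.006 * fine_elev
        ss_res = np.sum((pred - truth) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999

    def test_exposure_response_recovered(self):
        resp = 3.0 * self.mean + 1.0
        res = meso.TpsModel(self.X, resp).fit()
        fine = np.column_stack([np.full(100, 100.0), np.full(100, 0.5),
                                np.linspace(0.05, 0.95, 100)])
        pred = res.predict(fine, warn_extrapolation=False)
        truth = 3.0 * fine[:, 2] + 1.0
        assert np.max(np.abs(pred - truth) / np.abs(truth)) <= 0.01

    def test_interpolates_training_data_at_zero_smoothing(self):
        rng = np.random.default_rng(1)
        resp = rng.normal(0, 1, 16)
        res = meso.TpsModel(self.X, resp).fit(smoothing=0.0)
        np.testing.assert_allclose(res.predict(self.X, warn_extrapolation=False),
                                   resp, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="coarse cells"):
            meso.TpsModel(self.X[:5], np.zeros(5))


class TestMesoGrid:
    def _fixture(self):
        n = 16
        dem_vals = np.tile(np.linspace(200, 0, n)[:, None], (1, n))
        dem = RasterGrid(dem_vals.astype(np.float32), 0.0, n * 100.0, 100.0)
        mask = make_mask(np.ones((n, n)))
        mask.values[-1, :] = 0.0
        exp = meso.coastal_exposure(mask, 700.0, 8)
        return dem, mask, exp

    def test_zero_differential_returns_sst(self):
        dem, mask, exp = self._fixture()
        rng = np.random.default_rng(0)
        coarse_elev = rng.uniform(0, 200, 12)
        X = np.column_stack([coarse_elev, rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)])
        res = meso.TpsModel(X, np.zeros(12)).fit()
        out = meso.predict_mesoclimate_grid(res, dem, exp, 225.0, sst=10.0, mask=mask)
        land = mask.land
        np.testing.assert_allclose(out.values[land], 10.0, atol=1e-6)
        assert np.isnan(out.values[~land]).all()

    def test_lapse_only_model_analytic_value(self):
        dem, mask, exp = self._fixture()
        rng = np.random.default_rng(0)
        coarse_elev = np.linspace(0, 250, 12)
        X = np.column_stack([coarse_elev, np.full(12, 0.3), np.full(12, 0.3)])
        res = meso.TpsModel(X, -0.006 * coarse_elev).fit()
        out = meso.predict_mesoclimate_grid(res, dem, exp, 225.0, sst=10.0, mask=mask)
        i, j = 8, 8  # elevation ~ 93.3 m; fine exposure differs from training
        elev_ij = float(dem.values[i, j])
        # the affine part in elevation must dominate: sst + lapse * z
        assert out.values[i, j] == pytest.approx(10.0 - 0.006 * elev_ij, abs=0.05)

    def test_smooth_field(self):
        dem, mask, exp = self._fixture()
        rng = np.random.default_rng(2)
        coarse_elev = np.linspace(0, 250, 12)
        X = np.column_stack([coarse_elev, rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)])
        res = meso.TpsModel(X, -0.006 * coarse_elev + rng.normal(0, 0.1, 12)).fit()
        out = meso.predict_mesoclimate_grid(res, dem, exp, 225.0, sst=10.0, mask=mask)
        v = out.values[:-2, :]  # away from the coast row
        # neighbouring cells with near-identical covariates stay within 0.1 C
        dcol = np.abs(np.diff(v, axis=1))
        assert np.nanmax(dcol) < 0.25


class TestPrecipDownscaling:
    def _coarse(self, n_cells=4, days=92, seed=0):
        rng = np.random.default_rng(seed)
        dates = pd.date_range("2001-06-01", periods=days, freq="D")
        base = rng.gamma(0.7, 5.0, days) * (rng.uniform(size=days) < 0.4)
        cols = {c: base * (1 + 0.05 * c) for c in range(n_cells)}
        df = pd.DataFrame(cols, index=dates)
        xy = np.array([[500.0 + 1000 * c, 800.0] for c in range(n_cells)])
        return df, xy

    def test_uniform_elevation_copies_nearest_coarse(self):
        df, xy = self._coarse()
        fine = RasterGrid(np.zeros((8, 8), dtype=np.float32), 0.0, 800.0, 100.0)
        out = meso.downscale_precipitation(df, np.full(4, 50.0), fine, xy)
        # fine column j nearest coarse cell: all x < 1000 -> cell 0, etc.
        got = out.values[:, 4, 0]
        np.testing.assert_allclose(got, df[0].to_numpy(), atol=1e-5)

    def test_totals_follow_linear_elevation_relation(self):
        df, xy = self._coarse(n_cells=12)
        xy = np.array([[500.0 + 400 * c, 800.0] for c in range(12)])
        elev = np.linspace(0, 220, 12)
        scale = 1.0 + 0.002 * elev  # monthly totals linear in elevation
        for c in range(12):
            df[c] = df[0] * scale[c] / scale[0]
        fine_vals = np.tile(np.linspace(0, 220, 8)[:, None], (1, 8))
        fine = RasterGrid(fine_vals.astype(np.float32), 0.0, 800.0, 100.0)
        out = meso.downscale_precipitation(df, elev, fine, xy)
        months = pd.DatetimeIndex(out.time.to_index()).month
        for row in (1, 6):
            z = fine_vals[row, 0]
            expect = df[0].groupby(df.index.month).sum().iloc[0] \
                * (1 + 0.002 * z) / scale[0]
            got = out.values[months == 6, row, 0].sum()
            assert got == pytest.approx(expect, rel=0.01)

    def test_output_non_negative(self):
        df, xy = self._coarse()
        fine_vals = np.tile(np.linspace(0, 150, 8)[:, None], (1, 8))
        fine = RasterGrid(fine_vals.astype(np.float32), 0.0, 800.0, 100.0)
        out = meso.downscale_precipitation(df, np.linspace(0, 150, 4), fine, xy)
        assert (out.values >= 0).all()
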
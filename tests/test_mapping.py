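"""Daily SVR maps, aggregation, phenology maps, driver attribution."""

import numpy as np
import pandas as pd
import pytest

import vineclim as vc
from vineclim.bioclim import canopy_winkler
from vineclim.errors import (InsufficientDataError, InvalidParameterError,
                             OutOfBoundsError)
from vineclim.grids import COVARIATE_NAMES
from vineclim.mapping import (aggregate_maps, drivers_ols, extract_at_points,
                              fit_daily_model, map_validate, pheno_map,
                              predict_grid)
from vineclim.synth import gen_dem


@pytest.fixture(scope="module")
def grid():
    return gen_dem(seed=21, nx=16, ny=16)


@pytest.fixture(scope="module")
def covariates(grid):
    rng = np.random.default_rng(0)
    flat = rng.choice(grid.n_pixels, size=16, replace=False)
    rows, cols = np.unravel_index(flat, grid.shape)
    meta = pd.DataFrame({"sensor_id": [f"s{i:02d}" for i in range(16)],
                         "row": rows, "col": cols})
    return extract_at_points(grid, meta)


class TestExtract:
    def test_pixel_center_extracts_that_pixel(self, grid):
        meta = pd.DataFrame({"sensor_id": ["p"],
                             "x": [grid.pixel_center(4, 9)[0]],
                             "y": [grid.pixel_center(4, 9)[1]]})
        out = extract_at_points(grid, meta)
        assert (out.loc[0, "row"], out.loc[0, "col"]) == (4, 9)
        assert out.loc[0, "elevation"] == grid.layers["elevation"][4, 9]

    def test_order_independent_and_idempotent(self, grid, covariates):
        meta = covariates[["sensor_id", "row", "col"]]
        shuffled = meta.sample(frac=1, random_state=1)
        out = extract_at_points(grid, shuffled).sort_values("sensor_id")
        ref = covariates.sort_values("sensor_id")
        assert np.allclose(out[list(COVARIATE_NAMES)].to_numpy(),
                           ref[list(COVARIATE_NAMES)].to_numpy())

    def test_out_of_extent_sensor_named(self, grid):
        meta = pd.DataFrame({"sensor_id": ["rogue"], "x": [1e6], "y": [0.0]})
        with pytest.raises(OutOfBoundsError, match="rogue"):
            extract_at_points(grid, meta)


class TestDailyModel:
    def test_noiseless_linear_relationship_recovered(self, grid, covariates):
        values = pd.Series(0.05 * covariates["elevation"].to_numpy() + 4.0,
                           index=covariates["sensor_id"])
        model = fit_daily_model(values, covariates, epsilon=0.01)
        pred = model.predict(covariates[list(COVARIATE_NAMES)].to_numpy())
        assert np.allclose(pred, values.to_numpy(), atol=0.1)

    def test_constant_field_predicts_constant_grid(self, grid, covariates):
        values = pd.Series(9.0, index=covariates["sensor_id"])
        model = fit_daily_model(values, covariates)
        out = predict_grid(model, grid)
        assert np.allclose(out, 9.0, atol=0.05)

    def test_sensor_order_does_not_matter(self, grid, covariates):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(10, 2, len(covariates)),
                           index=covariates["sensor_id"])
        m1 = fit_daily_model(values, covariates)
        m2 = fit_daily_model(values.sample(frac=1, random_state=3), covariates)
        # identical up to the numerical tolerance of the SVR solver
        assert np.allclose(predict_grid(m1, grid), predict_grid(m2, grid),
                           atol=0.01)

    def test_too_few_sensors_raise(self, covariates):
        values = pd.Series(10.0, index=covariates["sensor_id"][:5])
        with pytest.raises(InsufficientDataError):
            fit_daily_model(values, covariates)

    def test_training_fidelity_bound(self, grid, covariates):
        rng = np.random.default_rng(2)
        values = pd.Series(0.04 * covariates["elevation"].to_numpy()
                           + rng.normal(0, 0.3, len(covariates)),
                           index=covariates["sensor_id"])
        model = fit_daily_model(values, covariates)
        out = predict_grid(model, grid)
        at_sensors = out[covariates["row"], covariates["col"]]
        bound = model.epsilon + 3 * max(model.train_residual_sd, 0.1)
        assert np.all(np.abs(at_sensors - values.to_numpy()) <= bound)

    def test_shuffled_labels_destroy_spatial_signal(self, grid, covariates):
        truth = 0.06 * grid.layers["elevation"]
        values = pd.Series(truth[covariates["row"], covariates["col"]],
                           index=covariates["sensor_id"])
        rng = np.random.default_rng(5)
        shuffled = pd.Series(rng.permutation(values.to_numpy()),
                             index=values.index)
        good = predict_grid(fit_daily_model(values, covariates, epsilon=0.01), grid)
        bad = predict_grid(fit_daily_model(shuffled, covariates, epsilon=0.01), grid)
        r_good = np.corrcoef(good.ravel(), truth.ravel())[0, 1]
        r_bad = np.corrcoef(bad.ravel(), truth.ravel())[0, 1]
        assert r_good > 0.9
        assert abs(r_bad) < 0.4


@pytest.fixture(scope="module")
def scene_maps(small_scene, clean_small):
    clean, _ = clean_small
    cov = extract_at_points(small_scene.grid, small_scene.meta)
    dates = pd.date_range("2018-03-01", "2018-12-31", freq="D")
    maps, skipped = vc.fit_predict_daily_maps(clean, cov, small_scene.grid,
                                              dates=dates, min_sensors=8)
    return small_scene, cov, dates, maps, skipped


class TestMapsPipeline:
    """Daily maps fitted on a real synthetic scene."""

    def test_regime_amplitude_ordering_in_maps(self, scene_maps):
        sc, cov, dates, maps, _ = scene_maps
        regime = sc.true_fields.weather.set_index("date")["regime"]
        amp = {d: maps[("tn", d)].max() - maps[("tn", d)].min()
               for v, d in maps if v == "tn"}
        amp = pd.Series(amp)
        by = amp.groupby(regime.reindex(amp.index))
        assert by.mean()["clear_calm"] > by.mean()["cloudy"]

    def test_seasonal_mean_map_identity_on_single_day(self, scene_maps):
        sc, cov, dates, maps, _ = scene_maps
        day = pd.DatetimeIndex([dates[10]])
        out = aggregate_maps(maps, day, op="mean", variable="tn")
        assert np.array_equal(out, maps[("tn", dates[10])])

    def test_pixelwise_winkler_equals_series_oracle(self, scene_maps):
        sc, cov, dates, maps, _ = scene_maps
        window = pd.date_range("2018-04-01", "2018-10-31", freq="D")
        cwi_map = aggregate_maps(maps, window, op="winkler_sum")
        r, c = 7, 7
        have = [d for d in window if ("tn", d) in maps and ("tx", d) in maps]
        assert len(have) >= 0.95 * len(window)
        tm = pd.Series({d: (maps[("tn", d)][r, c] + maps[("tx", d)][r, c]) / 2
                        for d in have})
        assert cwi_map[r, c] == pytest.approx(canopy_winkler(tm, 2018)["value"])

    def test_average_of_identical_maps_is_identity(self, scene_maps):
        sc, cov, dates, maps, _ = scene_maps
        m = maps[("tn", dates[0])]
        stack = {("tn", d): m for d in dates[:4]}
        out = aggregate_maps(stack, dates[:4], op="mean", variable="tn")
        assert np.allclose(out, m)

    def test_missing_days_beyond_tolerance_raise(self, scene_maps):
        sc, cov, dates, maps, _ = scene_maps
        window = pd.date_range("2019-04-01", "2019-04-30", freq="D")
        with pytest.raises(InvalidParameterError, match="missing"):
            aggregate_maps(maps, window, op="mean", variable="tn")


class TestPhenoMap:
    def ident_models(self):
        return {v: vc.CorrectionModel(v, 1.0, 0.0, 1.0, 100, 0.0)
                for v in ("tn", "tx")}

    def constant_maps(self, tn=14.0, tx=26.0):
        dates = pd.date_range("2018-03-01", "2018-12-31", freq="D")
        shape = (6, 6)
        maps = {}
        for d in dates:
            maps[("tn", d)] = np.full(shape, tn)
            maps[("tx", d)] = np.full(shape, tx)
        return maps, dates

    def test_constant_maps_give_constant_pheno(self):
        maps, dates = self.constant_maps()
        out = pheno_map(maps, dates, self.ident_models())
        for stage in ("flowering", "veraison"):
            assert np.all(out[stage] == out[stage].flat[0])
        assert np.all(out["flowering"] <= out["veraison"])

    def test_warmer_year_is_never_later(self):
        maps, dates = self.constant_maps()
        warm = {k: v + 2.0 for k, v in maps.items()}
        base = pheno_map(maps, dates, self.ident_models())
        early = pheno_map(warm, dates, self.ident_models())
        for stage in ("flowering", "veraison"):
            assert np.all(early[stage] <= base[stage])

    def test_cold_pixels_never_reach_threshold(self):
        maps, dates = self.constant_maps(tn=-2.0, tx=2.0)
        out = pheno_map(maps, dates, self.ident_models())
        assert np.isnan(out["veraison"]).all()


class TestDriversOLS:
    def test_single_driver_takes_all_variance(self, covariates):
        values = pd.Series(2.0 * covariates["elevation"].to_numpy(),
                           index=covariates["sensor_id"])
        out = drivers_ols(values, covariates)
        share = out.set_index("covariate")["variance_share"]
        assert share["elevation"] == pytest.approx(1.0, abs=1e-6)
        assert out.set_index("covariate")["coefficient"]["elevation"] > 0

    def test_shares_sum_to_model_r2(self, covariates):
        rng = np.random.default_rng(4)
        values = pd.Series(0.03 * covariates["elevation"].to_numpy()
                           + rng.normal(0, 1, len(covariates)),
                           index=covariates["sensor_id"])
        out = drivers_ols(values, covariates)
        total = out["variance_share"].sum()
        assert total == pytest.approx(out.attrs["r2"])
        assert 0 <= total <= 1 + 1e-9

    def test_elevation_sign_flips_between_regimes(self, small_scene, clean_small,
                                                  sensor_covariates):
        sc = small_scene
        clean, _ = clean_small
        weather = sc.true_fields.weather.set_index("date")
        ok = clean[(clean.variable == "tn") & (clean.qc == "pass")
                   & (clean.source != "filled")]
        signs = {}
        for regime in ("clear_calm", "cloudy"):
            days = weather.index[(weather["regime"] == regime)
                                 & (weather["amplitude_scale"]
                                    > weather["amplitude_scale"].quantile(0.1))]
            coefs = []
            for d in days[:25]:
                vals = ok[ok.date == d].groupby("sensor_id")["value"].mean()
                if len(vals) < 10:
                    continue
                out = drivers_ols(vals, sensor_covariates)
                coefs.append(out.set_index("covariate")["coefficient"]["elevation"])
            signs[regime] = np.median(coefs)
        assert signs["clear_calm"] > 0
        assert signs["cloudy"] < 0

    def test_collinear_design_raises(self, covariates):
        broken = covariates.copy()
        broken["eastness"] = broken["northness"] * 2.0
        values = pd.Series(np.arange(len(broken), dtype=float),
                           index=broken["sensor_id"])
        with pytest.raises(InvalidParameterError, match="collinear"):
            drivers_ols(values, broken)


def test_map_validation_zero_when_obs_equal_extraction(small_scene, clean_small,
                                                       sensor_covariates):
    maps = {"flowering": np.full(small_scene.grid.shape, 155.0),
            "veraison": np.full(small_scene.grid.shape, 228.0)}
    obs = []
    for r in sensor_covariates.itertuples():
        obs.append((r.sensor_id, 2018, "flowering", 155))
        obs.append((r.sensor_id, 2018, "veraison", 228))
    obs = pd.DataFrame(obs, columns=["sensor_id", "year", "stage", "doy"])
    out = map_validate(maps, obs, sensor_covariates, 2018)
    assert (out["rmse_days"] == 0).all()
    shifted = map_validate(maps, obs.assign(doy=obs["doy"] + 3),
                           sensor_covariates, 2018)
    assert (shifted["rmse_days"] >= 3).all()
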
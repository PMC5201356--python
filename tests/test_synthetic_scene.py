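"""Synthetic-scene generator: marginal shapes, station geometry, forward model."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwrpm25.grid import EARTH_RADIUS_KM, GridSpec
from gwrpm25.synthetic_scene import (
    CONSTANT_BETA,
    CoefSpec,
    SceneConfig,
    constant_coefficient_config,
    generate_coefficient_surfaces,
    generate_covariates,
    generate_observations,
    generate_stations,
    simulate,
    smooth_unit_field,
)


class TestCoefficientSurfaces:
    def test_constant_spec_gives_constant_surface(self):
        cfg = replace(SceneConfig(), coef_spec={"revised_aod": CoefSpec(base=2.0)})
        truth = generate_coefficient_surfaces(cfg)
        assert np.all(truth.surfaces["revised_aod"] == 2.0)

    def test_deterministic_given_seed(self):
        cfg = SceneConfig(seed=42)
        a = generate_coefficient_surfaces(cfg)
        b = generate_coefficient_surfaces(cfg)
        for name in a.surfaces:
            np.testing.assert_array_equal(a.surfaces[name], b.surfaces[name])

    def test_long_length_scale_field_is_smooth_at_one_step(self):
        # 500 km correlation length on a 3 km grid: adjacent cells nearly equal
        field = smooth_unit_field((400, 400), sigma_cells=500.0 / 3.0,
                                  rng=np.random.default_rng(0))
        lag1 = np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1]
        assert lag1 > 0.99

    def test_length_scale_below_grid_spacing_rejected(self):
        cfg = replace(
            SceneConfig(grid_res_km=50.0),
            coef_spec={"intercept": CoefSpec(base=1.0, amplitude=1.0, length_scale_km=30.0)},
        )
        with pytest.raises(ValueError, match="grid spacing"):
            generate_coefficient_surfaces(cfg)


@pytest.fixture(scope="module")
def fields():
    cfg = SceneConfig(grid_res_km=25.0, n_days=3, seed=5)
    return generate_covariates(cfg)


class TestCovariateMarginals:
    @pytest.mark.parametrize("name", ["AOD_true", "PBLH", "NO2", "EVI"])
    def test_right_skewed_marginals(self, fields, name):
        assert stats.skew(fields[name].values.ravel()) > 0

    def test_pressure_bimodal_two_separated_modes(self, fields):
        from sklearn.mixture import GaussianMixture

        ps = fields["PS"].values.ravel().reshape(-1, 1)
        assert ps.size >= 10_000
        gm = GaussianMixture(n_components=2, random_state=0).fit(ps)
        mu = np.sort(gm.means_.ravel())
        pooled_sd = np.sqrt(gm.covariances_.ravel().mean())
        assert mu[1] - mu[0] > 2.0 * pooled_sd

    def test_physical_ranges(self, fields):
        assert float(fields["RH"].min()) >= 0 and float(fields["RH"].max()) <= 100
        assert float(fields["PS"].min()) > 0
        assert float(fields["PBLH"].min()) > 0
        assert float(fields["EVI"].min()) >= -0.2 and float(fields["EVI"].max()) <= 1.0

    def test_evi_constant_within_16_day_composite(self):
        cfg = SceneConfig(n_days=18, seed=2)
        fields = generate_covariates(cfg)
        evi = fields["EVI"].values
        np.testing.assert_array_equal(evi[0], evi[15])
        assert not np.array_equal(evi[0], evi[16])

    def test_deterministic_given_seed(self):
        cfg = SceneConfig(n_days=2, seed=9)
        a = generate_covariates(cfg)
        b = generate_covariates(cfg)
        for name in a.data_vars:
            np.testing.assert_array_equal(a[name].values, b[name].values)


class TestStations:
    def test_uniform_nn_distance_matches_poisson_expectation(self):
        # homogeneous point process on the spherical patch: E[d_NN] = 0.5/sqrt(lambda)
        cfg = SceneConfig(n_stations=10_000, station_clustering=0.0, seed=1)
        st = generate_stations(cfg)
        lam_lon = np.radians(st["lon"].to_numpy())
        lam_lat = np.radians(st["lat"].to_numpy())
        xyz = EARTH_RADIUS_KM * np.column_stack(
            [
                np.cos(lam_lat) * np.cos(lam_lon),
                np.cos(lam_lat) * np.sin(lam_lon),
                np.sin(lam_lat),
            ]
        )
        from scipy.spatial import cKDTree

        chord, _ = cKDTree(xyz).query(xyz, k=2)
        arc = 2.0 * EARTH_RADIUS_KM * np.arcsin(chord[:, 1] / (2.0 * EARTH_RADIUS_KM))
        lon_min, lon_max, lat_min, lat_max = cfg.bbox
        area = (
            EARTH_RADIUS_KM**2
            * np.radians(lon_max - lon_min)
            * (np.sin(np.radians(lat_max)) - np.sin(np.radians(lat_min)))
        )
        expected = 0.5 / np.sqrt(cfg.n_stations / area)
        assert abs(arc.mean() - expected) / expected < 0.10

    def test_clustered_network_has_heavier_right_tail(self):
        from scipy.spatial import cKDTree

        def nn_distances(clustering, seed):
            cfg = SceneConfig(n_stations=2000, station_clustering=clustering, seed=seed)
            st = generate_stations(cfg)
            pts = np.column_stack([st["lon"], st["lat"]])
            d, _ = cKDTree(pts).query(pts, k=2)
            return d[:, 1]

        skew_uniform = stats.skew(nn_distances(0.0, 3))
        skew_clustered = stats.skew(nn_distances(0.9, 3))
        assert skew_clustered > skew_uniform

    def test_all_inside_bbox_and_deterministic(self):
        cfg = SceneConfig(n_stations=300, station_clustering=0.8, seed=6)
        a = generate_stations(cfg)
        b = generate_stations(cfg)
        pd.testing.assert_frame_equal(a, b)
        lon_min, lon_max, lat_min, lat_max = cfg.bbox
        assert a["lon"].between(lon_min, lon_max).all()
        assert a["lat"].between(lat_min, lat_max).all()


class TestForwardModel:
    def test_observation_equals_linear_predictor_without_noise(self):
        cfg = constant_coefficient_config(
            {"intercept": 10.0, "revised_aod": 2.0},
            n_stations=40,
            n_days=1,
            grid_res_km=100.0,
            noise_sd=0.0,
            seed=8,
        )
        scene = simulate(cfg)
        ms = scene.samples
        expected = np.maximum(10.0 + 2.0 * ms["revised_aod"].to_numpy(), 0.1)
        np.testing.assert_allclose(ms["pm25"].to_numpy(), expected, rtol=0, atol=1e-12)

    def test_global_ols_recovers_constant_coefficients(self, constant_noiseless_scene):
        ms = constant_noiseless_scene.samples
        X = np.column_stack(
            [np.ones(len(ms))]
            + [ms[c].to_numpy() for c in ("revised_aod", "st", "rh", "ps", "ws", "no2", "evi")]
        )
        beta = np.linalg.lstsq(X, ms["pm25"].to_numpy(), rcond=None)[0]
        truth = np.array([CONSTANT_BETA[n] for n in
                          ("intercept", "revised_aod", "st", "rh", "ps", "ws", "no2", "evi")])
        np.testing.assert_allclose(beta, truth, rtol=1e-8)

    def test_negative_values_truncated_and_flagged(self):
        cfg = constant_coefficient_config(
            {"intercept": -50.0}, n_stations=40, n_days=1, grid_res_km=100.0,
            noise_sd=0.0, seed=1,
        )
        scene = simulate(cfg)
        assert (scene.samples["pm25"] == 0.1).all()
        assert scene.samples["truncated"].all()

    def test_fully_missing_dt_leaves_db_unaffected(self):
        cfg = replace(
            constant_coefficient_config(CONSTANT_BETA, seed=2),
            n_stations=40, n_days=1, grid_res_km=100.0,
            dt_missing_frac=1.0, db_missing_frac=0.0,
        )
        scene = simulate(cfg)
        assert scene.dt_grids[0].n_valid == 0
        assert scene.db_grids[0].n_valid == scene.db_grids[0].mask.size

    def test_block_average_matches_fine_mean_without_missingness(self):
        cfg = replace(
            constant_coefficient_config(CONSTANT_BETA, seed=4),
            n_stations=40, n_days=1, grid_res_km=100.0,
            dt_missing_frac=0.0, db_missing_frac=0.0, db_block_factor=3,
        )
        scene = simulate(cfg)
        db = scene.db_grids[0]
        fine = scene.covariates["AOD_true"].isel(time=0).values
        f = cfg.db_block_factor
        trimmed = fine[: db.grid.nlat * f, : db.grid.nlon * f]
        assert abs(np.nanmean(db.values) - trimmed.mean()) <= 1e-10

    def test_scene_bit_identical_for_identical_config(self):
        cfg = SceneConfig(n_stations=30, n_days=2, grid_res_km=150.0, seed=13)
        a = simulate(cfg)
        b = simulate(cfg)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.dt_grids[0].values, b.dt_grids[0].values)
        np.testing.assert_array_equal(a.dt_grids[0].qa, b.dt_grids[0].qa)
        np.testing.assert_array_equal(a.db_grids[1].values, b.db_grids[1].values)

    def test_station_outside_grid_rejected(self):
        cfg = SceneConfig(n_stations=30, n_days=1, grid_res_km=150.0, seed=1)
        truth = generate_coefficient_surfaces(cfg)
        cov = generate_covariates(cfg)
        stations = generate_stations(cfg)
        stations.loc[0, "lon"] = cfg.bbox[1] + 5.0
        with pytest.raises(ValueError, match="outside"):
            generate_observations(truth, cov, stations, cfg)


def test_grid_cell_lookup_is_half_open():
    grid = GridSpec(lon_min=100.0, lat_min=20.0, dlon=0.5, dlat=0.5, nlon=4, nlat=4)
    row, col = grid.cell_of(100.5, 20.5)  # exactly on an interior edge
    assert (row, col) == (1, 1)
    row, col = grid.cell_of(102.0 - 1e-9, 22.0 - 1e-9)
    assert (row, col) == (3, 3)
    row, col = grid.cell_of(102.0, 20.5)  # on the outer edge: outside
    assert row == -1
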
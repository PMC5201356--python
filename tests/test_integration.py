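"""Covariate integration: AOD revision, kriging, temporal match, collocation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from gwrpm25.grid import GridSpec, haversine_km
from gwrpm25.integration import (
    MATCHED_COLUMNS,
    Variogram,
    build_matched_samples,
    collocate,
    kriging_resample,
    ordinary_kriging,
    revise_aod,
    temporal_match,
    wind_speed,
)


class TestWindSpeed:
    @pytest.mark.parametrize("u,v,expected", [(3, 4, 5), (0, 0, 0), (-5, 12, 13)])
    def test_known_triples(self, u, v, expected):
        assert wind_speed(u, v) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-60, 60), st.floats(-60, 60))
    def test_nonnegative_and_sign_invariant(self, u, v):
        ws = wind_speed(u, v)
        assert ws >= 0
        assert ws == pytest.approx(wind_speed(-u, -v))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            wind_speed(np.nan, 1.0)


class TestReviseAOD:
    @pytest.mark.parametrize("aod,pblh,expected", [(0.5, 1000.0, 0.5), (0.0, 250.0, 0.0), (0.8, 500.0, 1.6)])
    def test_boundary_layer_normalisation(self, aod, pblh, expected):
        assert revise_aod(aod, pblh) == pytest.approx(expected)

    def test_nonpositive_pblh_rejected(self):
        with pytest.raises(ValueError, match="PBLH"):
            revise_aod(0.5, 0.0)


class TestOrdinaryKriging:
    def test_constant_field_reproduced_exactly(self):
        lon = np.array([100.0, 101.0, 102.0, 100.5])
        lat = np.array([30.0, 30.5, 31.0, 31.5])
        val = np.full(4, 7.0)
        out = ordinary_kriging(lon, lat, val, np.array([100.8]), np.array([30.7]))
        assert out[0] == pytest.approx(7.0, abs=1e-9)

    def test_exact_at_data_point_with_zero_nugget(self):
        lon = np.array([100.0, 101.0, 102.0])
        lat = np.array([30.0, 30.5, 31.0])
        val = np.array([1.0, 3.2, 2.0])
        out = ordinary_kriging(lon, lat, val, np.array([101.0]), np.array([30.5]))
        assert out[0] == pytest.approx(3.2, abs=1e-12)

    def test_five_point_system_matches_hand_assembled_solve(self, rng):
        # independent oracle: assemble the ordinary-kriging system explicitly
        lon = 100.0 + rng.uniform(0, 2, 5)
        lat = 30.0 + rng.uniform(0, 2, 5)
        val = rng.uniform(10, 20, 5)
        vg = Variogram(range_km=150.0, sill=4.0, nugget=0.0)
        tlon, tlat = np.array([101.1]), np.array([30.9])

        n = 5
        a = np.zeros((n + 1, n + 1))
        for i in range(n):
            for j in range(n):
                h = haversine_km(lon[i], lat[i], lon[j], lat[j])
                a[i, j] = vg.nugget + vg.sill * (1 - np.exp(-h / vg.range_km))
            a[i, n] = 1.0
            a[n, i] = 1.0
        b = np.zeros(n + 1)
        for i in range(n):
            h = haversine_km(tlon[0], tlat[0], lon[i], lat[i])
            b[i] = vg.nugget + vg.sill * (1 - np.exp(-h / vg.range_km))
        b[n] = 1.0
        lam = np.linalg.solve(a, b)[:n]
        expected = float(lam @ val)

        out = ordinary_kriging(lon, lat, val, tlon, tlat, variogram=vg)
        assert out[0] == pytest.approx(expected, abs=1e-10)

    def test_targets_beyond_search_radius_masked(self):
        out = ordinary_kriging(
            np.array([100.0]), np.array([30.0]), np.array([5.0]),
            np.array([100.0, 110.0]), np.array([30.0, 40.0]),
            variogram=Variogram(range_km=50.0, sill=1.0),
        )
        assert out[0] == pytest.approx(5.0)
        assert np.isnan(out[1])

    def test_resample_exact_at_coincident_grid_node(self):
        # resample-then-extract equals extract-from-native when the target
        # cell centre coincides with a source cell centre (zero nugget)
        src = GridSpec(lon_min=100.0, lat_min=30.0, dlon=1.0, dlat=1.0, nlon=4, nlat=4)
        values = np.arange(16, dtype=float).reshape(4, 4)
        # half-resolution target offset so every other centre coincides
        tgt = GridSpec(lon_min=100.25, lat_min=30.25, dlon=0.5, dlat=0.5, nlon=7, nlat=7)
        out = kriging_resample((values, src), tgt)
        # target centre (100.5, 30.5) coincides with source cell (0, 0)
        assert out[0, 0] == pytest.approx(values[0, 0], abs=1e-9)
        assert out[2, 2] == pytest.approx(values[1, 1], abs=1e-9)


def _met_dataset():
    lat = [30.25, 30.75]
    lon = [100.25, 100.75]
    times = pd.date_range("2014-01-02 00:00", periods=4, freq="6h")
    st_vals = np.stack([np.full((2, 2), 280.0 + i) for i in range(4)])
    return xr.Dataset(
        {"ST": (("time", "lat", "lon"), st_vals)},
        coords={"time": times, "lat": lat, "lon": lon},
    )


class TestTemporalMatch:
    def test_six_hourly_meteorology_takes_0600_utc_slice(self):
        ds = _met_dataset()
        out = temporal_match(ds, "2014-01-02")
        assert out["ST"][0, 0] == 281.0  # the 06:00 UTC field

    def test_evi_composite_window_contains_date(self):
        starts = pd.DatetimeIndex(["2014-01-01", "2014-01-17"])
        evi = xr.Dataset(
            {"EVI": (("time", "lat", "lon"), np.stack([np.full((1, 1), 0.3), np.full((1, 1), 0.6)]))},
            coords={"time": starts, "lat": [30.0], "lon": [100.0]},
        )
        assert temporal_match(evi, "2014-01-20")["EVI"][0, 0] == 0.6
        assert temporal_match(evi, "2014-01-16")["EVI"][0, 0] == 0.3

    def test_date_outside_range_rejected(self):
        ds = _met_dataset()
        with pytest.raises(KeyError):
            temporal_match(ds, "2014-02-01")


def _daily_grids(grid, aod=0.5):
    shape = grid.shape
    return {
        "AOD": np.full(shape, aod),
        "PBLH": np.full(shape, 1000.0),
        "ST": np.full(shape, 285.0),
        "RH": np.full(shape, 60.0),
        "PS": np.full(shape, 101300.0),
        "u": np.full(shape, 3.0),
        "v": np.full(shape, 4.0),
        "NO2": np.full(shape, 1.0),
        "EVI": np.full(shape, 0.4),
    }


class TestCollocate:
    grid = GridSpec(lon_min=100.0, lat_min=30.0, dlon=0.5, dlat=0.5, nlon=4, nlat=4)

    def stations(self, lon, lat):
        return pd.DataFrame(
            {"station_id": [f"S{i}" for i in range(len(lon))], "lon": lon, "lat": lat,
             "pm25": np.full(len(lon), 50.0)}
        )

    def test_row_carries_cell_values_with_derived_fields(self):
        st = self.stations([100.25], [30.25])
        out = collocate(st, _daily_grids(self.grid), self.grid, "2014-01-01")
        assert list(out.columns) == MATCHED_COLUMNS
        row = out.iloc[0]
        assert row["revised_aod"] == pytest.approx(0.5)  # 0.5 / (1000 m / 1000)
        assert row["ws"] == pytest.approx(5.0)
        assert row["st"] == 285.0

    def test_position_within_cell_does_not_matter(self):
        grids = _daily_grids(self.grid)
        grids["AOD"] = np.arange(16, dtype=float).reshape(4, 4) / 10.0
        a = collocate(self.stations([100.51], [30.51]), grids, self.grid, "2014-01-01")
        b = collocate(self.stations([100.99], [30.99]), grids, self.grid, "2014-01-01")
        assert a.iloc[0]["revised_aod"] == b.iloc[0]["revised_aod"]

    def test_missing_aod_drops_row(self):
        grids = _daily_grids(self.grid)
        grids["AOD"] = np.full(self.grid.shape, np.nan)
        out = collocate(self.stations([100.25], [30.25]), grids, self.grid, "2014-01-01")
        assert len(out) == 0

    def test_station_outside_grid_dropped_with_warning(self):
        st = self.stations([100.25, 140.0], [30.25, 30.25])
        with pytest.warns(UserWarning, match="outside"):
            out = collocate(st, _daily_grids(self.grid), self.grid, "2014-01-01")
        assert len(out) == 1

    def test_retained_count_matches_mask_intersection_oracle(self, rng):
        grids = _daily_grids(self.grid)
        for name in ("AOD", "NO2", "EVI"):
            vals = grids[name].copy()
            vals[rng.uniform(size=self.grid.shape) < 0.4] = np.nan
            grids[name] = vals
        lon = rng.uniform(100.0, 102.0, 60)
        lat = rng.uniform(30.0, 32.0, 60)
        st = self.stations(lon, lat)
        out = collocate(st, grids, self.grid, "2014-01-01")
        rows, cols = self.grid.cell_of(lon, lat)
        expected = sum(
            1
            for r, c in zip(rows, cols)
            if r >= 0 and all(np.isfinite(grids[n][r, c]) for n in grids)
        )
        assert len(out) == expected

    def test_complete_case_rows_all_finite(self, noisy_scene):
        from gwrpm25.aod_fusion import fuse_products

        scene = noisy_scene
        fused = [
            fuse_products(dt, db, method="bilinear")
            for dt, db in zip(scene.dt_grids, scene.db_grids)
        ]
        station_days = scene.samples[["station_id", "lon", "lat", "date", "pm25"]]
        ms = build_matched_samples(
            station_days, scene.covariates, fused, scene.config.grid, dates=scene.dates
        )
        assert len(ms) > 0
        assert np.isfinite(ms[MATCHED_COLUMNS[4:]].to_numpy(dtype=float)).all()

    def test_all_aod_missing_yields_zero_rows(self):
        cfg_grid = self.grid
        grids = _daily_grids(cfg_grid)
        grids["AOD"] = np.full(cfg_grid.shape, np.nan)
        st = self.stations([100.1, 101.1, 101.9], [30.1, 31.1, 31.9])
        out = collocate(st, grids, cfg_grid, "2014-01-01")
        assert out.empty
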
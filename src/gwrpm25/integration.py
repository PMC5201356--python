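"""Covariate integration: kriging resampling, AOD revision, collocation.

Brings every covariate onto the common analysis grid, applies the
boundary-layer revision of the fused AOD (``Revised_AOD = AOD / PBLH[km]``),
computes wind speed from the u/v components, performs the temporal matching
(06:00 UTC synoptic slice for meteorology, daily AOD/NO2, the containing
16-day composite for EVI), and extracts one complete-case design row per
station-day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

from .aod_fusion import AODGrid
from .grid import GridSpec, haversine_km, local_xy_km

logger = logging.getLogger(__name__)

#: exact column order of the serialized matched-sample table
MATCHED_COLUMNS = [
    "station_id",
    "lon",
    "lat",
    "date",
    "pm25",
    "revised_aod",
    "st",
    "rh",
    "ps",
    "ws",
    "no2",
    "evi",
]

OVERPASS_UTC_HOUR = 6  # ~14:00 local time at the satellite overpass


@dataclass(frozen=True)
class StationRecord:
    """One ground-monitor observation."""

    station_id: str
    lon: float
    lat: float
    date: pd.Timestamp
    pm25: float  # ug/m3, > 0


def wind_speed(u, v):
    """Wind speed (m/s) from u/v components: ``sqrt(u^2 + v^2)``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite wind components")
    return np.hypot(u, v)


def revise_aod(aod, pblh_m, pblh_to_km: float = 1000.0):
    """Boundary-layer-normalised AOD: ``AOD / (PBLH / 1000)``.

    Dividing the column AOD by the mixed-layer depth (in km) converts it
    toward a near-surface extinction proxy; the divisor convention is a
    single configurable constant (``pblh_to_km``).
    """
    aod = np.asarray(aod, dtype=float)
    pblh_m = np.asarray(pblh_m, dtype=float)
    if np.any(pblh_m <= 0):
        raise ValueError("PBLH must be positive")
    if np.any(aod[np.isfinite(aod)] < 0):
        raise ValueError("AOD must be non-negative")
    return aod / (pblh_m / pblh_to_km)


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variogram:
    """Exponential variogram ``gamma(h) = nugget + sill * (1 - exp(-h/range))``."""

    range_km: float
    sill: float
    nugget: float = 0.0

    def __call__(self, h_km) -> np.ndarray:
        h = np.asarray(h_km, dtype=float)
        return self.nugget + self.sill * (1.0 - np.exp(-h / self.range_km))


def default_variogram(src_lon, src_lat, src_val) -> Variogram:
    """Default parameters: sill = field variance, range = 3x mean source
    spacing (mean nearest-neighbour distance), zero nugget."""
    n = len(src_val)
    sill = float(np.var(src_val))
    if sill == 0.0:
        sill = 1.0  # constant field; any positive sill reproduces it exactly
    if n >= 2:
        x, y = local_xy_km(src_lon, src_lat, float(np.mean(src_lat)))
        tree = cKDTree(np.column_stack([x, y]))
        d_nn, _ = tree.query(np.column_stack([x, y]), k=2)
        spacing = float(np.mean(d_nn[:, 1]))
    else:
        spacing = 1.0
    return Variogram(range_km=max(3.0 * spacing, 1e-6), sill=sill)


def ordinary_kriging(
    src_lon,
    src_lat,
    src_val,
    tgt_lon,
    tgt_lat,
    variogram: Variogram | None = None,
    max_neighbors: int = 12,
    search_radius_km: float | None = None,
    coincident_tol_km: float = 1e-6,
) -> np.ndarray:
    """Ordinary-kriging prediction at target points.

    Solves the standard system with the unbiasedness constraint in each
    target's neighbourhood (up to ``max_neighbors`` nearest sources inside
    ``search_radius_km``, default 3x the variogram range).  Exact at source
    points when the nugget is zero; targets with no source support within the
    search radius come back NaN.  A singular neighbourhood system falls back
    to inverse-distance weighting with a logged warning.
    """
    src_lon = np.asarray(src_lon, dtype=float)
    src_lat = np.asarray(src_lat, dtype=float)
    src_val = np.asarray(src_val, dtype=float)
    tgt_lon = np.asarray(tgt_lon, dtype=float)
    tgt_lat = np.asarray(tgt_lat, dtype=float)
    if src_val.size == 0:
        return np.full(tgt_lon.shape, np.nan)
    vg = variogram if variogram is not None else default_variogram(src_lon, src_lat, src_val)
    radius = search_radius_km if search_radius_km is not None else 3.0 * vg.range_km

    lat_ref = float(np.mean(src_lat))
    sx, sy = local_xy_km(src_lon, src_lat, lat_ref)
    tx, ty = local_xy_km(tgt_lon, tgt_lat, lat_ref)
    tree = cKDTree(np.column_stack([sx, sy]))
    k = min(max_neighbors, len(src_val))
    # query radius padded: projection distances only order neighbours
    dist_proj, idx = tree.query(np.column_stack([tx, ty]), k=k, distance_upper_bound=1.25 * radius)
    if k == 1:
        dist_proj = dist_proj[:, None]
        idx = idx[:, None]

    out = np.full(tgt_lon.shape[0], np.nan)
    n_fallback = 0
    for t in range(len(out)):
        neigh = idx[t][np.isfinite(dist_proj[t])]
        if neigh.size == 0:
            continue
        d = haversine_km(tgt_lon[t], tgt_lat[t], src_lon[neigh], src_lat[neigh])
        inside = d <= radius
        neigh, d = neigh[inside], d[inside]
        if neigh.size == 0:
            continue
        hit = d <= coincident_tol_km
        if vg.nugget == 0.0 and hit.any():
            out[t] = src_val[neigh[hit][0]]  # exact interpolation at a datum
            continue
        m = neigh.size
        gamma = vg(
            haversine_km(
                src_lon[neigh][:, None],
                src_lat[neigh][:, None],
                src_lon[neigh][None, :],
                src_lat[neigh][None, :],
            )
        )
        a = np.empty((m + 1, m + 1))
        a[:m, :m] = gamma
        a[m, :m] = 1.0
        a[:m, m] = 1.0
        a[m, m] = 0.0
        b = np.empty(m + 1)
        b[:m] = vg(d)
        b[m] = 1.0
        try:
            sol = np.linalg.solve(a, b)
            lam = sol[:m]
            if not np.all(np.isfinite(lam)):
                raise np.linalg.LinAlgError
            out[t] = float(lam @ src_val[neigh])
        except np.linalg.LinAlgError:
            n_fallback += 1
            w = 1.0 / np.maximum(d, coincident_tol_km) ** 2
            out[t] = float(w @ src_val[neigh] / w.sum())
    if n_fallback:
        logger.warning(
            "ordinary kriging: %d singular systems fell back to inverse-distance weighting",
            n_fallback,
        )
    return out


def kriging_resample(
    field,
    target_grid: GridSpec,
    variogram: Variogram | None = None,
    max_neighbors: int = 12,
    search_radius_km: float | None = None,
):
    """Resample a gridded field onto ``target_grid`` by ordinary kriging.

    ``field`` may be an :class:`~gwrpm25.aod_fusion.AODGrid` or a pair
    ``(values_2d, GridSpec)``; NaN cells are treated as missing sources.
    Returns a 2-D array on the target grid (NaN outside the search radius).
    """
    if isinstance(field, AODGrid):
        values, grid = field.values, field.grid
    else:
        values, grid = field
    values = np.asarray(values, dtype=float)
    lon2d, lat2d = grid.mesh_centers()
    valid = np.isfinite(values)
    if not valid.any():
        return np.full(target_grid.shape, np.nan)
    tlon2d, tlat2d = target_grid.mesh_centers()
    out = ordinary_kriging(
        lon2d[valid],
        lat2d[valid],
        values[valid],
        tlon2d.ravel(),
        tlat2d.ravel(),
        variogram=variogram,
        max_neighbors=max_neighbors,
        search_radius_km=search_radius_km,
    )
    return out.reshape(target_grid.shape)


# ---------------------------------------------------------------------------
# temporal matching and collocation
# ---------------------------------------------------------------------------

def temporal_match(fields: xr.Dataset, date) -> dict[str, np.ndarray]:
    """Select each covariate's grid for one calendar date.

    Meteorology (ST, RH, PS, u, v, PBLH): the 06:00 UTC synoptic slice of the
    date (nearest available time within the date's 6-hourly samples).  Daily
    fields (NO2, AOD variants): that date's field.  EVI: the 16-day composite
    whose window contains the date.  Raises KeyError if the date is outside a
    field's time range.
    """
    date = pd.Timestamp(date).normalize()
    out: dict[str, np.ndarray] = {}
    for name in fields.data_vars:
        da = fields[name]
        times = pd.DatetimeIndex(da["time"].values)
        if name == "EVI":
            starts = times.normalize()
            i = int(np.searchsorted(starts, date, side="right")) - 1
            if i < 0 or date >= starts[i] + pd.Timedelta(days=16):
                raise KeyError(f"date {date.date()} outside EVI composite windows")
            out[name] = da.isel(time=i).values
        elif name in ("ST", "RH", "PS", "u", "v", "PBLH"):
            same_day = times.normalize() == date
            if not same_day.any():
                raise KeyError(f"date {date.date()} outside {name} time range")
            day_times = times[same_day]
            target = date + pd.Timedelta(hours=OVERPASS_UTC_HOUR)
            j = int(np.argmin(np.abs(day_times - target)))
            out[name] = da.sel(time=day_times[j]).values
        else:  # daily products: NO2, AOD_true, AOD
            same_day = times.normalize() == date
            if not same_day.any():
                raise KeyError(f"date {date.date()} outside {name} time range")
            out[name] = da.sel(time=times[same_day][0]).values
    return out


def collocate(
    stations: pd.DataFrame,
    daily_grids: dict[str, np.ndarray],
    grid: GridSpec,
    date,
    pblh_to_km: float = 1000.0,
) -> pd.DataFrame:
    """Extract one design row per station from the day's grids.

    ``stations`` must carry ``station_id, lon, lat, pm25``; each covariate is
    taken from the grid cell containing the station ("the pixel in which the
    monitor is located").  Rows with any missing covariate are dropped
    (complete-case); stations outside the grid are dropped with a warning.
    Wind speed and the PBLH revision of AOD are applied here.
    """
    required = {"AOD", "PBLH", "ST", "RH", "PS", "u", "v", "NO2", "EVI"}
    missing = required - set(daily_grids)
    if missing:
        raise KeyError(f"daily grids missing {sorted(missing)}")

    lon = stations["lon"].to_numpy()
    lat = stations["lat"].to_numpy()
    rows, cols = grid.cell_of(lon, lat)
    inside = rows >= 0
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} stations outside the grid extent; rows dropped")

    def cell(name):
        vals = np.full(len(stations), np.nan)
        vals[inside] = np.asarray(daily_grids[name], dtype=float)[rows[inside], cols[inside]]
        return vals

    aod = cell("AOD")
    pblh = cell("PBLH")
    with np.errstate(invalid="ignore", divide="ignore"):
        revised = np.where((pblh > 0) & np.isfinite(aod), aod / (pblh / pblh_to_km), np.nan)
    u, v = cell("u"), cell("v")
    out = pd.DataFrame(
        {
            "station_id": stations["station_id"].to_numpy(),
            "lon": lon,
            "lat": lat,
            "date": pd.Timestamp(date).normalize(),
            "pm25": stations["pm25"].to_numpy(),
            "revised_aod": revised,
            "st": cell("ST"),
            "rh": cell("RH"),
            "ps": cell("PS"),
            "ws": np.hypot(u, v),
            "no2": cell("NO2"),
            "evi": cell("EVI"),
        }
    )
    n0 = len(out)
    out = out.dropna().reset_index(drop=True)
    if len(out) < n0:
        logger.info("collocate %s: dropped %d of %d rows (incomplete covariates)",
                    pd.Timestamp(date).date(), n0 - len(out), n0)
    return out[MATCHED_COLUMNS]


def build_matched_samples(
    station_days: pd.DataFrame,
    covariates: xr.Dataset,
    fused_aod: dict | list,
    grid: GridSpec,
    dates=None,
    pblh_to_km: float = 1000.0,
) -> pd.DataFrame:
    """Assemble the full matched-sample table over all days.

    ``station_days`` holds station_id, lon, lat, date, pm25 (one row per
    station-day measurement); ``fused_aod`` maps each date (or day index) to
    a fused :class:`AODGrid` or a 2-D array on ``grid``.
    """
    if dates is None:
        dates = pd.DatetimeIndex(pd.unique(pd.to_datetime(station_days["date"]).dt.normalize()))
    frames = []
    for d, date in enumerate(dates):
        day_rows = station_days[pd.to_datetime(station_days["date"]).dt.normalize() == date]
        if day_rows.empty:
            continue
        grids = temporal_match(covariates, date)
        aod = fused_aod[date] if isinstance(fused_aod, dict) else fused_aod[d]
        grids["AOD"] = aod.values if isinstance(aod, AODGrid) else np.asarray(aod, dtype=float)
        grids.pop("AOD_true", None)
        frames.append(collocate(day_rows, grids, grid, date, pblh_to_km=pblh_to_km))
    if not frames:
        return pd.DataFrame(columns=MATCHED_COLUMNS)
    return pd.concat(frames, ignore_index=True)
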
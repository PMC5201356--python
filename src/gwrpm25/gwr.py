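"""Geographically weighted regression (GWR) with an adaptive Gaussian kernel.

GWR fits one weighted least-squares regression per location, with weights
that decay with great-circle distance, so every coefficient becomes a surface
``beta_k(l)`` instead of a single global number.  The kernel is adaptive: at
each calibration/prediction location the bandwidth is the distance to the
k-th nearest calibration point, so dense station clusters get narrow kernels
and sparse regions wide ones.  The neighbour count k is selected by
leave-one-out cross-validation (golden-section or exhaustive search).

Two predictor sets are built in: the full model
``PM2.5 ~ Revised_AOD + ST + RH + PS + WS + NO2 + EVI`` and the reduced
(meteorology-only) model without NO2 and EVI; arbitrary subsets are allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .grid import pairwise_distances_km

logger = logging.getLogger(__name__)

PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "full": ("revised_aod", "st", "rh", "ps", "ws", "no2", "evi"),
    "reduced": ("revised_aod", "st", "rh", "ps", "ws"),
    "+no2": ("revised_aod", "st", "rh", "ps", "ws", "no2"),
    "+evi": ("revised_aod", "st", "rh", "ps", "ws", "evi"),
}


def resolve_predictors(predictor_set) -> tuple[str, ...]:
    if isinstance(predictor_set, str):
        try:
            return PREDICTOR_SETS[predictor_set]
        except KeyError:
            raise ValueError(f"unknown predictor set {predictor_set!r}") from None
    return tuple(predictor_set)


@dataclass(frozen=True)
class GWRConfig:
    """Configuration of a GWR fit."""

    predictor_set: str | Sequence[str] = "full"
    k_range: tuple[int, int] | None = None  # default (p + 2, n - 1)
    search: Literal["golden", "grid"] = "golden"
    criterion: Literal["cv", "aicc"] = "cv"
    fit_scope: Literal["per-day", "pooled"] = "pooled"
    kernel_half: bool = False  # True: w = exp(-(d/b)^2 / 2)
    bandwidth_scale: float = 1.0  # multiplies the adaptive bandwidth (1e9 ~ OLS limit)
    ridge_eps_scale: float = 1e-10
    seed: int = 0

    @property
    def predictors(self) -> tuple[str, ...]:
        return resolve_predictors(self.predictor_set)


@dataclass
class GWRFit:
    """Per-location coefficient vectors plus bookkeeping.

    ``table`` has one row per calibration row: coordinates, date, observed
    and fitted PM2.5, the local bandwidth distance (km), a ridge flag, and
    one ``beta_*`` column per coefficient (intercept first).
    """

    k: int | dict
    table: pd.DataFrame
    predictors: tuple[str, ...]
    scope: str
    config: GWRConfig

    @property
    def coef_columns(self) -> list[str]:
        return ["beta_intercept"] + [f"beta_{p}" for p in self.predictors]

    def coefficients(self) -> np.ndarray:
        return self.table[self.coef_columns].to_numpy()


def design_matrix(samples: pd.DataFrame, predictors: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix with a leading column of ones, and the response vector."""
    X = np.column_stack(
        [np.ones(len(samples))] + [samples[p].to_numpy(dtype=float) for p in predictors]
    )
    y = samples["pm25"].to_numpy(dtype=float)
    return X, y


def gaussian_weights(distances_km, bandwidth_km: float, half: bool = False) -> np.ndarray:
    """Gaussian kernel weights ``exp(-(d/b)^2)`` (or ``exp(-(d/b)^2/2)``)."""
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.asarray(distances_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    q = (d / bandwidth_km) ** 2
    return np.exp(-0.5 * q) if half else np.exp(-q)


def _kth_distance(dists: np.ndarray, k: int, exclude: int | None = None) -> float:
    """Distance to the k-th nearest point, excluding one zero-distance self.

    Ties at the k-th distance are included by construction (the returned
    value is the tied distance).  If the k-th distance is zero (duplicate
    locations), the smallest positive distance is used instead so the kernel
    stays well-defined.
    """
    d = np.delete(dists, exclude) if exclude is not None else dists.copy()
    if k > d.size:
        raise ValueError(f"k = {k} exceeds the {d.size} available neighbours")
    d.sort()
    b = float(d[k - 1])
    if b <= 0.0:
        pos = d[d > 0]
        if pos.size == 0:
            raise ValueError("all candidate neighbours are at zero distance")
        b = float(pos[0])
    return b


def adaptive_bandwidth(lon: float, lat: float, cal_lon, cal_lat, k: int) -> float:
    """Adaptive bandwidth: great-circle distance to the k-th nearest
    calibration location, excluding a zero-distance self if present."""
    d = pairwise_distances_km([lon], [lat], cal_lon, cal_lat)[0]
    zero = np.flatnonzero(d <= 1e-12)
    exclude = int(zero[0]) if zero.size else None
    return _kth_distance(d, k, exclude=exclude)


def local_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    ridge_eps_scale: float = 1e-10,
    return_info: bool = False,
):
    """Weighted least squares ``argmin sum_i w_i (y_i - x_i beta)^2``.

    Solved by QR/SVD on the square-root-weighted, column-scaled system; a
    near-singular weighted design gets a tiny ridge
    (``ridge_eps_scale * trace(X'WX)/p`` on the scaled system) and is
    flagged.  Raises LinAlgError if the system stays unsolvable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p = X.shape[1]
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    scale = np.linalg.norm(Xw, axis=0)
    scale[scale == 0.0] = 1.0
    A = Xw / scale
    beta_s, _, rank, sv = np.linalg.lstsq(A, yw, rcond=None)
    used_ridge = False
    if rank < p:
        ata = A.T @ A
        eps = ridge_eps_scale * np.trace(ata) / p
        beta_s = np.linalg.solve(ata + eps * np.eye(p), A.T @ yw)
        used_ridge = True
    beta = beta_s / scale
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError("weighted design is singular")
    return (beta, used_ridge) if return_info else beta


def _loocv_rss(D: np.ndarray, X: np.ndarray, y: np.ndarray, k: int, config: GWRConfig) -> float:
    """Leave-one-out CV residual sum of squares for neighbour count k."""
    n = len(y)
    rss = 0.0
    for i in range(n):
        try:
            b = _kth_distance(D[i], k, exclude=i)
            w = gaussian_weights(D[i], b, half=config.kernel_half)
            w[i] = 0.0
            beta = local_fit(X, y, w, config.ridge_eps_scale)
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        r = y[i] - X[i] @ beta
        rss += r * r
    return rss


def _resolve_k_range(config: GWRConfig, n: int, p: int) -> tuple[int, int]:
    if config.k_range is not None:
        k_min, k_max = config.k_range
    else:
        k_min, k_max = p + 2, n - 1
    k_min = max(k_min, p + 2)
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        raise ValueError(f"empty bandwidth range ({k_min}, {k_max}) for n = {n}")
    return k_min, k_max


def select_bandwidth(
    samples: pd.DataFrame,
    config: GWRConfig,
    D: np.ndarray | None = None,
) -> int:
    """Select the neighbour count k* minimising the LOO-CV residual sum of
    squares over the configured range; ties break toward larger k (smoother).

    Golden-section search assumes the CV profile is unimodal in k; the
    exhaustive ``grid`` search makes no such assumption.
    """
    X, y = design_matrix(samples, config.predictors)
    if D is None:
        lon = samples["lon"].to_numpy()
        lat = samples["lat"].to_numpy()
        D = pairwise_distances_km(lon, lat, lon, lat)
    k_min, k_max = _resolve_k_range(config, len(y), X.shape[1])

    cache: dict[int, float] = {}

    def score(k: int) -> float:
        if k not in cache:
            cache[k] = _loocv_rss(D, X, y, k, config)
        return cache[k]

    if config.search == "grid" or (k_max - k_min) <= 4:
        candidates = range(k_min, k_max + 1)
    else:
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        lo, hi = k_min, k_max
        while hi - lo > 3:
            x1 = int(round(hi - invphi * (hi - lo)))
            x2 = int(round(lo + invphi * (hi - lo)))
            x1 = min(max(x1, lo + 1), hi - 2)
            x2 = min(max(x2, x1 + 1), hi - 1)
            if score(x1) < score(x2):
                hi = x2
            else:
                lo = x1
        candidates = range(lo, hi + 1)

    best_k, best_s = None, np.inf
    for k in candidates:
        s = score(k)
        if s <= best_s:  # <=: ties go to the larger k
            best_k, best_s = k, s
    if best_k is None or not np.isfinite(best_s):
        raise ValueError("no candidate bandwidth produced a solvable fit")
    return best_k


def _fit_block(
    block: pd.DataFrame, config: GWRConfig, k: int | None
) -> tuple[pd.DataFrame, int]:
    """Fit every calibration location of one scope block (a day, or pooled)."""
    X, y = design_matrix(block, config.predictors)
    lon = block["lon"].to_numpy()
    lat = block["lat"].to_numpy()
    D = pairwise_distances_km(lon, lat, lon, lat)
    if k is None:
        k = select_bandwidth(block, config, D=D)

    n, p = X.shape
    betas = np.full((n, p), np.nan)
    fitted = np.full(n, np.nan)
    bandwidth = np.full(n, np.nan)
    ridge_flag = np.zeros(n, dtype=bool)
    masked = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            b = _kth_distance(D[i], k, exclude=i) * config.bandwidth_scale
            w = gaussian_weights(D[i], b, half=config.kernel_half)
            # self-weight 1: the calibration point's own row is included
            beta, used_ridge = local_fit(X, y, w, config.ridge_eps_scale, return_info=True)
        except (ValueError, np.linalg.LinAlgError):
            masked[i] = True
            continue
        betas[i] = beta
        fitted[i] = X[i] @ beta
        bandwidth[i] = b
        ridge_flag[i] = used_ridge
    if masked.any():
        logger.warning("fit_gwr: %d locations had insufficient neighbours; coefficients masked",
                       int(masked.sum()))

    out = block[["station_id", "lon", "lat", "date", "pm25"]].copy().reset_index(drop=True)
    out["fitted"] = fitted
    out["bandwidth_km"] = bandwidth
    out["ridge_flag"] = ridge_flag
    out["beta_intercept"] = betas[:, 0]
    for j, pname in enumerate(config.predictors):
        out[f"beta_{pname}"] = betas[:, j + 1]
    return out, k


def fit_gwr(samples: pd.DataFrame, config: GWRConfig, k: int | None = None) -> GWRFit:
    """Fit GWR at every calibration location.

    ``per-day`` scope fits each calendar date independently (bandwidth
    selected per day); ``pooled`` scope fits all rows together with purely
    spatial weights.  Pass ``k`` to skip bandwidth selection.
    """
    if len(samples) == 0:
        raise ValueError("no samples to fit")
    if config.fit_scope == "per-day":
        frames, ks = [], {}
        for date, block in samples.groupby(pd.to_datetime(samples["date"]).dt.normalize(), sort=True):
            tab, kd = _fit_block(block.reset_index(drop=True), config, k)
            frames.append(tab)
            ks[pd.Timestamp(date)] = kd
        table = pd.concat(frames, ignore_index=True)
        chosen: int | dict = ks if k is None else k
    else:
        table, chosen = _fit_block(samples.reset_index(drop=True), config, k)
    return GWRFit(k=chosen, table=table, predictors=config.predictors,
                  scope=config.fit_scope, config=config)


def predict(
    samples: pd.DataFrame,
    config: GWRConfig,
    targets: pd.DataFrame,
    k: int | None = None,
    extrapolation_factor: float = 3.0,
) -> pd.DataFrame:
    """Predict PM2.5 at target locations carrying full covariate rows.

    Each target gets its own local fit on the calibration data with the
    kernel centred at the target (bandwidth = distance to the k-th nearest
    calibration point from the target).  Targets whose nearest calibration
    point lies beyond ``extrapolation_factor x bandwidth`` are masked (NaN)
    and flagged as extrapolation.
    """
    if config.fit_scope == "per-day":
        preds = []
        for date, tblock in targets.groupby(pd.to_datetime(targets["date"]).dt.normalize(), sort=False):
            cal = samples[pd.to_datetime(samples["date"]).dt.normalize() == pd.Timestamp(date)]
            if cal.empty:
                raise ValueError(f"no calibration rows for date {date}")
            preds.append(_predict_block(cal, config, tblock, k, extrapolation_factor))
        return pd.concat(preds).sort_index()
    return _predict_block(samples, config, targets, k, extrapolation_factor)


def _predict_block(samples, config, targets, k, extrapolation_factor):
    X, y = design_matrix(samples, config.predictors)
    cal_lon = samples["lon"].to_numpy()
    cal_lat = samples["lat"].to_numpy()
    if k is None:
        k = select_bandwidth(samples, config)
    Xt = np.column_stack(
        [np.ones(len(targets))] + [targets[p].to_numpy(dtype=float) for p in config.predictors]
    )
    Dt = pairwise_distances_km(
        targets["lon"].to_numpy(), targets["lat"].to_numpy(), cal_lon, cal_lat
    )
    n_t = len(targets)
    yhat = np.full(n_t, np.nan)
    bandw = np.full(n_t, np.nan)
    extrap = np.zeros(n_t, dtype=bool)
    for t in range(n_t):
        d = Dt[t]
        # a target coincident with a calibration point uses the same bandwidth
        # rule as calibration fitting (zero-distance self excluded)
        zero = np.flatnonzero(d <= 1e-12)
        try:
            b = _kth_distance(d, k, exclude=int(zero[0]) if zero.size else None)
            b *= config.bandwidth_scale
        except ValueError:
            extrap[t] = True
            continue
        if d.min() > extrapolation_factor * b:
            extrap[t] = True
            continue
        w = gaussian_weights(d, b, half=config.kernel_half)
        try:
            beta = local_fit(X, y, w, config.ridge_eps_scale)
        except np.linalg.LinAlgError:
            extrap[t] = True
            continue
        yhat[t] = Xt[t] @ beta
        bandw[t] = b
    out = pd.DataFrame(
        {"prediction": yhat, "bandwidth_km": bandw, "extrapolated": extrap},
        index=targets.index,
    )
    return out


def predict_grid(
    samples: pd.DataFrame,
    config: GWRConfig,
    daily_grids: dict[str, np.ndarray],
    grid,
    k: int | None = None,
    pblh_to_km: float = 1000.0,
) -> np.ndarray:
    """Predict a full PM2.5 grid for one day from gridded covariates.

    ``daily_grids`` must carry AOD, PBLH, ST, RH, PS, u, v, NO2, EVI on the
    analysis grid; cells with any missing covariate stay NaN.
    """
    lon2d, lat2d = grid.mesh_centers()
    with np.errstate(invalid="ignore", divide="ignore"):
        revised = daily_grids["AOD"] / (daily_grids["PBLH"] / pblh_to_km)
    fields = {
        "revised_aod": revised,
        "st": daily_grids["ST"],
        "rh": daily_grids["RH"],
        "ps": daily_grids["PS"],
        "ws": np.hypot(daily_grids["u"], daily_grids["v"]),
        "no2": daily_grids["NO2"],
        "evi": daily_grids["EVI"],
    }
    valid = np.ones(grid.shape, dtype=bool)
    for name in config.predictors:
        valid &= np.isfinite(fields[name])
    targets = pd.DataFrame(
        {"lon": lon2d[valid], "lat": lat2d[valid]}
        | {name: fields[name][valid] for name in config.predictors}
    )
    out = np.full(grid.shape, np.nan)
    if targets.empty:
        return out
    pred = _predict_block(samples, config, targets, k, extrapolation_factor=3.0)
    out[valid] = pred["prediction"].to_numpy()
    return out
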
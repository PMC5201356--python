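"""10-fold cross-validation and agreement diagnostics.

The data are split into k balanced random folds; each fold is predicted by a
GWR model fitted on the other k-1 folds (bandwidth selection repeated inside
every training set, so no information leaks from the held-out fold).  The
pooled held-out predictions are summarised by

* MAE (ug/m3),
* two R^2 definitions — the squared Pearson correlation of the
  predicted-vs-measured scatter ("regression R^2", the headline number) and
  ``1 - SSE/SST``,
* the ordinary-least-squares line of predicted on measured, and
* the demarcation point ``intercept / (1 - slope)`` where that line crosses
  the y = x reference — the PM2.5 level separating the overestimation regime
  (below it, when slope < 1 and intercept > 0) from underestimation above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwr import GWRConfig, fit_gwr, predict

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Pooled k-fold cross-validation outcome.

    ``table`` has one row per sample: fold id, measured pm25, held-out
    prediction.  The regression orientation is predicted-on-measured.
    """

    table: pd.DataFrame
    r2_regression: float
    r2_one_minus_sse: float
    mae: float
    slope: float
    intercept: float
    demarcation: float | None
    n_rows: int
    n_excluded: int
    k_folds: int
    seed: int
    orientation: str = "predicted-on-measured"

    def summary(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_excluded": self.n_excluded,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "r2_regression": self.r2_regression,
            "r2_one_minus_sse": self.r2_one_minus_sse,
            "mae": self.mae,
            "slope": self.slope,
            "intercept": self.intercept,
            "demarcation": self.demarcation,
            "orientation": self.orientation,
        }


def kfold_split(n_rows: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random balanced partition into k folds (sizes differ by at most 1)."""
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_rows)
    fold = np.empty(n_rows, dtype=int)
    base = n_rows // k
    extra = n_rows % k
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        fold[order[start : start + size]] = f
        start += size
    return fold


def metrics(measured, predicted) -> dict[str, float]:
    """Agreement metrics between measured and predicted vectors.

    Returns slope/intercept of the OLS line of predicted on measured, both
    R^2 definitions, and the MAE.  Raises on zero variance in the measured
    values (the regression line is undefined).
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in metrics input")
    if np.var(y) == 0.0:
        raise ValueError("measured values have zero variance")
    fit = stats.linregress(y, yhat)  # predicted regressed on measured
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2_regression": float(fit.rvalue) ** 2,
        "r2_one_minus_sse": 1.0 - sse / sst,
        "mae": float(np.mean(np.abs(y - yhat))),
    }


def demarcation_point(slope: float, intercept: float) -> float | None:
    """Intersection of the fitted line with y = x: ``intercept / (1 - slope)``.

    Returns None when slope = 1 (the lines are parallel and never cross).
    """
    if abs(slope - 1.0) < 1e-12:
        return None
    return intercept / (1.0 - slope)


def cross_validate(
    samples: pd.DataFrame,
    config: GWRConfig,
    k_folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of a GWR configuration.

    Bandwidth selection happens inside each training set.  Held-out rows that
    cannot be predicted (extrapolation mask) are excluded from the metrics
    with a logged count.
    """
    samples = samples.reset_index(drop=True)
    fold = kfold_split(len(samples), k=k_folds, seed=seed)
    predictions = np.full(len(samples), np.nan)
    for f in range(k_folds):
        test = fold == f
        train = samples.loc[~test]
        pred = predict(train, config, samples.loc[test])
        predictions[test] = pred["prediction"].to_numpy()

    table = pd.DataFrame(
        {
            "station_id": samples["station_id"],
            "date": samples["date"],
            "fold_id": fold,
            "pm25": samples["pm25"],
            "prediction": predictions,
        }
    )
    ok = np.isfinite(predictions)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("cross_validate: %d held-out rows unpredictable (extrapolation); excluded",
                       n_excluded)
    m = metrics(table.loc[ok, "pm25"], table.loc[ok, "prediction"])
    return CVResult(
        table=table,
        r2_regression=m["r2_regression"],
        r2_one_minus_sse=m["r2_one_minus_sse"],
        mae=m["mae"],
        slope=m["slope"],
        intercept=m["intercept"],
        demarcation=demarcation_point(m["slope"], m["intercept"]),
        n_rows=int(ok.sum()),
        n_excluded=n_excluded,
        k_folds=k_folds,
        seed=seed,
    )


def in_sample_metrics(samples: pd.DataFrame, config: GWRConfig, k: int | None = None) -> dict[str, float]:
    """Metrics of the in-sample GWR fitted values (no held-out assessment)."""
    fit = fit_gwr(samples, config, k=k)
    ok = np.isfinite(fit.table["fitted"])
    return metrics(fit.table.loc[ok, "pm25"], fit.table.loc[ok, "fitted"])
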
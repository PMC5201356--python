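"""Annual aggregation of daily PM2.5 grids and air-quality classification.

Daily prediction grids (NaN where no estimate) are averaged per cell over the
days with a valid value; a configurable minimum coverage fraction masks cells
estimated on too few days (default 0: any available day counts).  Annual
means are classified into half-open concentration bands; the default band
edges ``{20, 35, 60, 80}`` ug/m3 bracket the WHO IT-1 / national level-2
threshold of 35 ug/m3, with 35.0 itself counting as exceeding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .grid import GridSpec

logger = logging.getLogger(__name__)

#: ug/m3 band edges; 35 is the WHO IT-1 / Chinese level-2 annual standard
DEFAULT_THRESHOLDS = (20.0, 35.0, 60.0, 80.0)


@dataclass
class AnnualGrid:
    """Per-cell annual mean PM2.5 with coverage bookkeeping."""

    mean: np.ndarray  # ug/m3, NaN where masked
    n_valid_days: np.ndarray
    coverage_fraction: np.ndarray
    grid: GridSpec
    min_coverage: float

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "pm25_annual_mean": (("lat", "lon"), self.mean),
                "n_valid_days": (("lat", "lon"), self.n_valid_days),
                "coverage_fraction": (("lat", "lon"), self.coverage_fraction),
            },
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
            attrs={"min_coverage": self.min_coverage, "units": "ug m-3"},
        )


def annual_average(daily_grids, grid: GridSpec, min_coverage: float = 0.0) -> AnnualGrid:
    """Average daily grids cell-wise over their valid days.

    ``daily_grids`` is a sequence of 2-D arrays (NaN = no estimate) or a 3-D
    array stacked on axis 0.  Cells whose fraction of valid days falls below
    ``min_coverage`` are masked.
    """
    stack = np.asarray(daily_grids, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need at least one daily grid")
    n_days = stack.shape[0]
    valid = np.isfinite(stack)
    n_valid = valid.sum(axis=0)
    coverage = n_valid / n_days
    with np.errstate(invalid="ignore"):
        total = np.where(valid, stack, 0.0).sum(axis=0)
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
    mean = np.where(coverage >= min_coverage if min_coverage > 0 else n_valid > 0, mean, np.nan)
    if not np.isfinite(mean).any():
        logger.warning("annual_average: no cell has any valid day; grid fully masked")
    return AnnualGrid(
        mean=mean,
        n_valid_days=n_valid,
        coverage_fraction=coverage,
        grid=grid,
        min_coverage=min_coverage,
    )


def classify_thresholds(annual: AnnualGrid, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Label each valid cell with its half-open concentration band.

    Band ``i`` is ``[t_{i-1}, t_i)`` with lower-inclusive edges, so a cell at
    exactly 35.0 ug/m3 falls in the exceeding band.  Masked cells get -1.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    labels = np.full(annual.mean.shape, -1, dtype=int)
    valid = np.isfinite(annual.mean)
    labels[valid] = np.digitize(annual.mean[valid], t, right=False)
    return labels
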
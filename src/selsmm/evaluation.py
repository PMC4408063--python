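"""Accuracy assessment of estimated FVC against plot-level field coverage.

Field plots (sized to match the pixel footprint) are paired with the single
pixel containing their coordinates; accuracy is summarized by the root mean
square error

    RMSE = sqrt( (1/N) sum_i (f'_i - f_i)^2 )

and the coefficient of determination R^2, taken as the squared Pearson
correlation between estimated and measured cover (identical to the R^2 of
the simple linear regression of estimated on measured).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fvc import FvcMap

__all__ = ["PlotRecord", "EvalResult", "read_plots", "write_plots",
           "sample_estimates_at_plots", "rmse", "r_squared_and_regression",
           "evaluate_fvc_map"]


@dataclass
class PlotRecord:
    """One field plot: id, map coordinates, measured cover fraction."""

    id: str
    x: float
    y: float
    measured_fvc: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("plot coordinates must be finite")
        if not 0.0 <= self.measured_fvc <= 1.0:
            raise ValueError("measured_fvc must lie in [0, 1]")


@dataclass
class EvalResult:
    """Paired-accuracy statistics of estimated vs measured cover."""

    n_pairs: int
    rmse: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float


def read_plots(path: str | Path) -> list[PlotRecord]:
    df = pd.read_csv(path)
    required = {"id", "x", "y", "measured_fvc"}
    if not required.issubset(df.columns):
        raise ValueError(f"plots CSV must have columns {sorted(required)}")
    return [PlotRecord(id=str(r.id), x=float(r.x), y=float(r.y),
                       measured_fvc=float(r.measured_fvc))
            for r in df.itertuples()]


def write_plots(plots: list[PlotRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([{"id": p.id, "x": p.x, "y": p.y,
                   "measured_fvc": p.measured_fvc} for p in plots]
                 ).to_csv(path, index=False)
    return path


def _world_to_pixel(geotransform: tuple | None, x: float, y: float
                    ) -> tuple[float, float]:
    """Invert the affine geotransform to fractional (row, col)."""
    if geotransform is None:
        geotransform = (0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    x0, dxc, dxr, y0, dyc, dyr = geotransform
    det = dxc * dyr - dxr * dyc
    if det == 0:
        raise ValueError("degenerate geotransform")
    col = ((x - x0) * dyr - (y - y0) * dxr) / det
    row = ((y - y0) * dxc - (x - x0) * dyc) / det
    return row, col


def sample_estimates_at_plots(fvc_map: FvcMap, plots: list[PlotRecord]
                              ) -> tuple[list[tuple[float, float]], list[str]]:
    """Pair each plot with the FVC of the pixel containing it.

    Returns (pairs, excluded_ids); ``pairs`` is [(estimated, measured), ...]
    in input order.  Plots outside the raster extent or on nodata pixels are
    excluded with a warning naming the plot id.
    """
    rows, cols = fvc_map.fvc.shape
    pairs: list[tuple[float, float]] = []
    excluded: list[str] = []
    for p in plots:
        r_f, c_f = _world_to_pixel(fvc_map.geotransform, p.x, p.y)
        r, c = int(np.floor(r_f)), int(np.floor(c_f))
        if not (0 <= r < rows and 0 <= c < cols):
            warnings.warn(f"plot {p.id!r} falls outside the raster extent",
                          stacklevel=2)
            excluded.append(p.id)
            continue
        if fvc_map.mask[r, c] or not np.isfinite(fvc_map.fvc[r, c]):
            warnings.warn(f"plot {p.id!r} falls on a nodata pixel",
                          stacklevel=2)
            excluded.append(p.id)
            continue
        pairs.append((float(fvc_map.fvc[r, c]), p.measured_fvc))
    return pairs, excluded


def rmse(pairs: list[tuple[float, float]]) -> float:
    """Root mean square error of (estimated, measured) pairs."""
    if len(pairs) == 0:
        raise ValueError("no pairs to evaluate")
    arr = np.asarray(pairs, dtype=float)
    return float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))


def r_squared_and_regression(pairs: list[tuple[float, float]]) -> EvalResult:
    """R^2 and the OLS regression of estimated on measured cover.

    R^2 is the squared Pearson correlation; slope/intercept/p_value come
    from ordinary least squares with a two-sided t-test on the slope.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs for regression")
    est, meas = arr[:, 0], arr[:, 1]
    if np.ptp(est) == 0 or np.ptp(meas) == 0:
        raise ValueError("zero variance in estimated or measured values")
    fit = stats.linregress(meas, est)
    return EvalResult(n_pairs=arr.shape[0], rmse=rmse(pairs),
                      r_squared=float(fit.rvalue ** 2),
                      slope=float(fit.slope), intercept=float(fit.intercept),
                      p_value=float(fit.pvalue))


def evaluate_fvc_map(fvc_map: FvcMap, plots: list[PlotRecord]) -> EvalResult:
    """Convenience: pair plots with the map and compute all statistics."""
    pairs, _ = sample_estimates_at_plots(fvc_map, plots)
    return r_squared_and_regression(pairs)
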
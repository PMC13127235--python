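"""Agreement statistics between vegetation indices and SIF/GPP references.

Per-pixel Pearson correlation maps against SIF, tower-footprint 3x3 window
means, 8-day averaging of daily reference series (with an optional uniform
time-axis shift for products whose calendar is offset), k-fold
cross-validated linear regression (R2 / RMSE / median bias), and
day-of-year-binned residual summaries across the phenological seasons.

Bias convention: ``bias = median(observed - estimated)``, so a *negative*
median bias means the VI-based model overestimates the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import composite_8day

__all__ = [
    "CVReport",
    "pearson_r",
    "pearson_map",
    "tower_window_mean",
    "align_to_8day",
    "cv_linear_regression",
    "residual_seasonal_bins",
    "DOY_BINS",
]

#: Seasonal residual bins (half-open; last closes at 366 to cover leap DOYs):
#: dormant, green-up, peak growing season, senescence, dormant.
DOY_BINS = (1, 60, 150, 240, 330, 366)


def pearson_r(x, y):
    """Product-moment correlation with pairwise missing removal.

    Returns NaN (with a warning) for fewer than 3 complete pairs or zero
    variance on either side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        warnings.warn("pearson_r: fewer than 3 complete pairs", stacklevel=2)
        return np.nan
    xv, yv = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    sx, sy = np.sqrt((xv * xv).sum()), np.sqrt((yv * yv).sum())
    if sx == 0 or sy == 0:
        warnings.warn("pearson_r: zero variance", stacklevel=2)
        return np.nan
    return float(np.clip((xv * yv).sum() / (sx * sy), -1.0, 1.0))


def pearson_map(vi, ref):
    """Per-pixel correlation of two co-registered (time, y, x) cubes.

    Returns ``(r_grid, summary)`` where the summary holds the median,
    interquartile range, and a fixed-bin histogram on [-1, 1] with step
    0.05 of the valid per-pixel correlations.
    """
    vi = np.asarray(vi, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if vi.shape != ref.shape:
        raise ValueError("cubes must share a shape")
    ok = np.isfinite(vi) & np.isfinite(ref)
    n = ok.sum(axis=0)
    xm = np.where(ok, vi, 0.0)
    ym = np.where(ok, ref, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = xm.sum(axis=0) / n
        mean_y = ym.sum(axis=0) / n
        dx = np.where(ok, vi - mean_x, 0.0)
        dy = np.where(ok, ref - mean_y, 0.0)
        cov = (dx * dy).sum(axis=0)
        r = cov / np.sqrt((dx * dx).sum(axis=0) * (dy * dy).sum(axis=0))
    r = np.where(n >= 3, r, np.nan)
    valid = r[np.isfinite(r)]
    edges = np.arange(-1.0, 1.0001, 0.05)
    hist, _ = np.histogram(valid, bins=edges)
    summary = {
        "median": float(np.median(valid)) if valid.size else np.nan,
        "iqr": float(np.subtract(*np.percentile(valid, [75, 25])))
        if valid.size else np.nan,
        "hist_edges": edges,
        "hist_counts": hist,
        "n_pixels": int(valid.size),
    }
    return r, summary


def tower_window_mean(cube, row: int, col: int):
    """Missing-ignoring mean of the 3x3 pixel window around a tower site.

    ``cube`` is (time, y, x). The site must sit at least one pixel from
    every edge (pad the cube or move the site otherwise).
    """
    cube = np.asarray(cube, dtype=float)
    _, ny, nx = cube.shape
    if not (1 <= row <= ny - 2 and 1 <= col <= nx - 2):
        raise ValueError(
            "tower window touches the grid edge: pad the cube or relocate "
            f"the site (row={row}, col={col}, grid {ny}x{nx})"
        )
    block = cube[:, row - 1 : row + 2, col - 1 : col + 2].reshape(cube.shape[0], -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=1)


def align_to_8day(values, doy, shift_days: float = 0.0,
                  year_length: int = 365):
    """Average a daily reference series onto the 8-day composite grid.

    ``shift_days`` uniformly shifts the series' time axis *before* binning
    (positive = later), supporting references whose calendar is offset from
    the composite grid; samples shifted outside [1, year_length] are
    dropped.
    """
    values = np.asarray(values, dtype=float)
    doy = np.asarray(doy, dtype=float) + shift_days
    keep = (doy >= 1) & (doy <= year_length)
    comp, _ = composite_8day(values[..., keep], doy[keep].astype(int),
                             np.ones(keep.sum(), dtype=bool),
                             year_length=year_length)
    return comp


@dataclass
class CVReport:
    """Pooled out-of-fold skill of a cross-validated linear regression."""

    r2: float
    rmse: float
    bias_median: float
    n: int
    k: int
    fold_assignments: np.ndarray
    predictions: np.ndarray


def cv_linear_regression(x, y, k: int = 10, seed: int = 0) -> CVReport:
    """k-fold cross-validated simple linear regression of y on x.

    Data are shuffled once (seeded) and split into k near-equal contiguous
    folds; each fold is predicted by the line fitted on the others. The
    pooled out-of-fold predictions give R2 = 1 - SS_res/SS_tot, RMSE, and
    the median bias ``median(y - yhat)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(order, k)):
        folds[idx] = f

    yhat = np.full(n, np.nan)
    for f in range(k):
        test = folds == f
        xt, yt = x[~test], y[~test]
        if np.ptp(xt) == 0:
            warnings.warn(f"fold {f}: constant predictor in training split; "
                          "fold skipped", stacklevel=2)
            continue
        b, a = np.polyfit(xt, yt, 1)
        yhat[test] = a + b * x[test]

    ok_pred = np.isfinite(yhat)
    resid = y[ok_pred] - yhat[ok_pred]
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y[ok_pred] - y[ok_pred].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid ** 2))) if resid.size else np.nan
    bias = float(np.median(resid)) if resid.size else np.nan
    return CVReport(r2=float(r2), rmse=rmse, bias_median=bias, n=n, k=k,
                    fold_assignments=folds, predictions=yhat)


def residual_seasonal_bins(residuals, doy) -> pd.DataFrame:
    """Median / IQR / count of residuals in the five phenological DOY bins.

    Bins: [1,60) dormant, [60,150) green-up, [150,240) peak season,
    [240,330) senescence, [330,366) dormant. DOY outside [1, 366) raises.
    """
    residuals = np.asarray(residuals, dtype=float)
    doy = np.asarray(doy, dtype=float)
    if np.any((doy < 1) | (doy >= 366)):
        raise ValueError("day of year must lie in [1, 366)")
    rows = []
    for lo, hi in zip(DOY_BINS[:-1], DOY_BINS[1:]):
        sel = (doy >= lo) & (doy < hi) & np.isfinite(residuals)
        r = residuals[sel]
        rows.append({
            "bin": f"[{lo},{hi})",
            "doy_lo": lo,
            "doy_hi": hi,
            "median": float(np.median(r)) if r.size else np.nan,
            "iqr": float(np.subtract(*np.percentile(r, [75, 25])))
            if r.size else np.nan,
            "count": int(r.size),
        })
    return pd.DataFrame(rows)
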
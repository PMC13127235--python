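"""Nonparametric trend inference on annual phenology series.

Theil–Sen median slope (robust to outliers, no distributional assumption)
paired with the Mann–Kendall monotone-trend test with tie correction.
Significance classing uses |Z| >= 1.96 (95 %) and |Z| > 2.56 (99 %) — the
2.56 figure, rather than the conventional 2.576, is kept deliberately to
match common remote-sensing practice and is noted in the methods document.

Regional summaries support both aggregation orders: the default fits the
trend to the region-mean annual series ("series-first", the treatment used
for basin-scale means), and pixel-level significance fractions are
reported separately from the per-pixel trend grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrendResult",
    "theil_sen",
    "mann_kendall",
    "trend_map",
    "region_summary",
    "Z_95",
    "Z_99",
]

Z_95 = 1.96
Z_99 = 2.56  # as printed in the remote-sensing convention followed here

SIG_LABELS = {0: "none", 1: "p<0.05", 2: "p<0.01"}


@dataclass
class TrendResult:
    slope: float
    s_stat: float
    var_s: float
    z: float
    sig_class: str
    n: int


def theil_sen(years, values) -> float:
    """Median of all pairwise slopes (v_j - v_i)/(y_j - y_i), i < j.

    Missing values are dropped pairwise; fewer than 2 points gives NaN.
    An even slope count returns the mean of the central two (np.median).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & np.isfinite(years)
    years, values = years[ok], values[ok]
    n = years.size
    if n < 2:
        return np.nan
    i, j = np.triu_indices(n, k=1)
    slopes = (values[j] - values[i]) / (years[j] - years[i])
    return float(np.median(slopes))


def mann_kendall(values) -> TrendResult:
    """Mann–Kendall test with tie-corrected variance.

    S = sum_{i<j} sign(v_j - v_i);
    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie groups;
    Z = (S-1)/sqrt(Var) for S > 0, (S+1)/sqrt(Var) for S < 0, else 0.

    Fewer than 4 non-missing values, or an all-tied series (Var = 0),
    yields Z = 0 and the "none" class.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 4:
        return TrendResult(np.nan, np.nan, np.nan, np.nan, "none", n)
    diff = np.sign(v[None, :] - v[:, None])
    s = float(np.triu(diff, k=1).sum())
    _, counts = np.unique(v, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        z = 0.0
    elif s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    if abs(z) > Z_99:
        sig = SIG_LABELS[2]
    elif abs(z) >= Z_95:
        sig = SIG_LABELS[1]
    else:
        sig = SIG_LABELS[0]
    return TrendResult(slope=np.nan, s_stat=s, var_s=float(var_s), z=float(z),
                       sig_class=sig, n=n)


def trend_map(annual, years=None, min_years: int = 4):
    """Per-pixel Theil–Sen slope and Mann–Kendall significance.

    ``annual`` is (year, y, x); pixels with fewer than ``min_years`` valid
    years come back missing. Returns a dict of grids: ``slope``, ``z``,
    ``sig`` (0 none / 1 p<0.05 / 2 p<0.01, -1 missing), ``n``.
    """
    annual = np.asarray(annual, dtype=float)
    n_years, ny, nx = annual.shape
    if years is None:
        years = np.arange(n_years)
    years = np.asarray(years, dtype=float)
    slope = np.full((ny, nx), np.nan)
    z = np.full((ny, nx), np.nan)
    sig = np.full((ny, nx), -1, dtype=int)
    nval = np.zeros((ny, nx), dtype=int)
    inv_sig = {v: k for k, v in SIG_LABELS.items()}
    for r in range(ny):
        for c in range(nx):
            series = annual[:, r, c]
            ok = np.isfinite(series)
            nval[r, c] = int(ok.sum())
            if nval[r, c] < min_years:
                continue
            slope[r, c] = theil_sen(years, series)
            mk = mann_kendall(series)
            z[r, c] = mk.z
            sig[r, c] = inv_sig[mk.sig_class]
    return {"slope": slope, "z": z, "sig": sig, "n": nval}


def region_summary(annual, regions, years=None, trends=None) -> pd.DataFrame:
    """Per-region trend table.

    For each region label the *regional* slope and significance come from
    the trend of the region-mean annual series (pixels averaged first).
    Pixel-level context comes from the per-pixel trend grid (``trends``;
    computed here when not supplied): the fraction of valid pixels that is
    significant at |Z| >= 1.96, and among those, the fractions advancing
    (slope < 0) and delaying (slope > 0).

    Empty regions yield a row of NaNs.
    """
    annual = np.asarray(annual, dtype=float)
    regions = np.asarray(regions)
    if regions.shape != annual.shape[1:]:
        raise ValueError("region mask must match the pixel grid")
    if years is None:
        years = np.arange(annual.shape[0])
    if trends is None:
        trends = trend_map(annual, years=years)

    rows = []
    for label in np.unique(regions):
        sel = regions == label
        if not sel.any():
            continue
        series = np.array([
            np.nanmean(annual[t][sel]) if np.isfinite(annual[t][sel]).any()
            else np.nan
            for t in range(annual.shape[0])
        ])
        slope = theil_sen(years, series)
        mk = mann_kendall(series)
        px_sig = trends["sig"][sel]
        px_slope = trends["slope"][sel]
        valid = px_sig >= 0
        signif = px_sig >= 1
        n_sig = int(signif.sum())
        rows.append({
            "region": label,
            "n_pixels": int(sel.sum()),
            "regional_slope": slope,
            "regional_z": mk.z,
            "regional_sig": mk.sig_class,
            "pct_significant": 100.0 * n_sig / valid.sum() if valid.any()
            else np.nan,
            "pct_sig_advancing": 100.0 * float(
                (px_slope[signif] < 0).sum()) / n_sig if n_sig else np.nan,
            "pct_sig_delaying": 100.0 * float(
                (px_slope[signif] > 0).sum()) / n_sig if n_sig else np.nan,
        })
    return pd.DataFrame(rows)
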
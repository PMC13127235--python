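"""Vegetation indices from surface reflectance.

Implements the three indices compared throughout the package — EVI, kernel
NDVI, and the Plant Phenology Index (PPI) — together with the supporting
pieces: the difference vegetation index DVI, the PPI gain factor K, a noon
solar-zenith helper, quality-filtered 8-day compositing, climatological
filling of a leading gap, and the per-pixel canopy-maximum DVI used by PPI.

Conventions
-----------
* Reflectances are dimensionless in [0, 1]; missing observations are NaN.
* All index functions propagate NaN and never raise on data values;
  only invalid *parameters* raise.
* The composite grid is fixed at day-of-year 1, 9, ..., 361 (46 windows per
  year, MODIS 8-day convention); the last window covers 5 days in a 365-day
  year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "COMPOSITE_START_DOY",
    "N_COMPOSITES",
    "PPIParams",
    "compute_evi",
    "compute_kndvi",
    "compute_dvi",
    "ppi_gain_k",
    "compute_ppi",
    "solar_zenith_noon",
    "composite_8day",
    "fill_leading_gap",
    "per_pixel_max_dvi",
]

#: Start day-of-year of each 8-day composite window (46 per year).
COMPOSITE_START_DOY = np.arange(1, 362, 8)
N_COMPOSITES = len(COMPOSITE_START_DOY)  # 46

#: Small positive guard for the EVI denominator.
_EVI_DENOM_GUARD = 1e-9


def compute_evi(nir, red, blue):
    """Enhanced Vegetation Index.

    EVI = 2.5 * (nir - red) / (nir + 6*red - 7.5*blue + 1), the standard
    MODIS coefficient set (gain 2.5, canopy background L = 1, aerosol
    resistance C1 = 6, C2 = 7.5).

    A denominator at or below ``1e-9`` (near-singular or negative) yields NaN
    rather than an unstable ratio; NaN inputs propagate.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    blue = np.asarray(blue, dtype=float)
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        evi = 2.5 * (nir - red) / denom
        evi = np.where(denom > _EVI_DENOM_GUARD, evi, np.nan)
    return evi[()] if evi.ndim == 0 else evi


def compute_kndvi(nir, red, sigma=None):
    """Kernel NDVI, tanh(((nir - red) / (2*sigma))**2).

    With the recommended length scale ``sigma = 0.5*(nir + red)`` (the
    default) this reduces exactly to tanh(NDVI**2), bounded in [0, 1).
    ``nir + red == 0`` (default sigma undefined) yields NaN.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if sigma is None:
        sigma = 0.5 * (nir + red)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = (nir - red) / (2.0 * sigma)
        out = np.tanh(arg * arg)
        out = np.where(sigma > 0, out, np.nan)
    return out[()] if out.ndim == 0 else out


def compute_dvi(nir, red):
    """Difference Vegetation Index, nir - red (NaN propagates)."""
    return np.asarray(nir, dtype=float) - np.asarray(red, dtype=float)


@dataclass
class PPIParams:
    """Parameters of the PPI transform for one pixel (or broadcastable grids).

    Attributes
    ----------
    M : float or ndarray
        Canopy maximum DVI, per pixel; the asymptotic DVI of a fully closed
        canopy, in practice estimated as the record maximum
        (:func:`per_pixel_max_dvi`). Must satisfy DVIs < M < 1.
    DVIs : float
        Bare-soil DVI; 0.09 by default.
    G : float
        Leaf-angular geometry function; 0.5 (spherical leaf-angle
        distribution) by default.
    dc : float
        Instantaneous diffuse fraction of solar radiation at zenith theta,
        in [0, 1]. Default 0 = pure direct beam.
    theta : float or ndarray
        Solar zenith angle in radians, [0, pi/2).
    eps : float
        Saturation clamp margin in DVI units: DVI is clamped to
        [DVIs, M - eps] before the log transform, capping PPI at
        K*ln((M - DVIs)/eps). The default 0.04 sits at roughly three times
        the noise scale of an 8-day composite DVI, so composites whose gap
        to the canopy maximum is indistinguishable from noise do not blow up
        the logarithm.
    """

    M: float | np.ndarray
    DVIs: float = 0.09
    G: float = 0.5
    dc: float = 0.0
    theta: float | np.ndarray = 0.0
    eps: float = 0.04

    def validate(self) -> None:
        M = np.asarray(self.M, dtype=float)
        finite = M[np.isfinite(M)]
        if finite.size and np.any(finite >= 1.0):
            raise ValueError("canopy maximum DVI must be < 1")
        if finite.size and np.any(finite <= self.DVIs):
            raise ValueError("canopy maximum DVI must exceed bare-soil DVIs")
        if not (0.0 <= self.dc <= 1.0):
            raise ValueError("diffuse fraction dc must lie in [0, 1]")
        th = np.asarray(self.theta, dtype=float)
        if np.any(th < 0) or np.any(th >= np.pi / 2):
            raise ValueError("solar zenith angle must lie in [0, pi/2)")
        if self.eps <= 0:
            raise ValueError("clamp margin eps must be positive")


def ppi_gain_k(theta, dc, G, M):
    """PPI gain factor K.

    K = [0.25*cos(theta) / ((1 - dc)*G + dc*cos(theta))] * (1 + M)/(1 - M)

    The first bracket is the angular/diffuse geometry term, the second the
    canopy-density amplification; K > 0 for valid parameters.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M[np.isfinite(M)] >= 1.0):
        raise ValueError("canopy maximum DVI must be < 1")
    cos_t = np.cos(np.asarray(theta, dtype=float))
    geom = 0.25 * cos_t / ((1.0 - dc) * G + dc * cos_t)
    out = geom * (1.0 + M) / (1.0 - M)
    return out[()] if np.ndim(out) == 0 else out


def compute_ppi(dvi, params: PPIParams, K=None):
    """Plant Phenology Index, -K * ln((M - DVI) / (M - DVIs)), in m^2 m^-2.

    DVI is clamped to [DVIs, M - eps] first, so PPI(DVIs) = 0, PPI is
    monotone non-decreasing in DVI, and the log singularity at DVI = M is
    capped at K*ln((M - DVIs)/eps). Parameter grids broadcast against
    ``dvi`` (e.g. per-pixel M, per-date theta). ``K`` overrides the gain
    computed from the geometry parameters when given.
    """
    params.validate()
    dvi = np.asarray(dvi, dtype=float)
    M = np.asarray(params.M, dtype=float)
    if K is None:
        K = ppi_gain_k(params.theta, params.dc, params.G, M)
    upper = M - params.eps
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.clip(dvi, params.DVIs, upper)
        # where eps pushes the upper clamp below DVIs, pixel is effectively
        # non-vegetated; the ratio would exceed 1 -> force PPI = 0
        d = np.where(upper <= params.DVIs, params.DVIs, d)
        ppi = -K * np.log((M - d) / (M - params.DVIs))
        ppi = np.where(np.isnan(dvi), np.nan, ppi)
    return ppi[()] if np.ndim(ppi) == 0 else ppi


def solar_zenith_noon(latitude_deg, doy):
    """Solar zenith angle at local solar noon, in radians.

    Uses the classical declination approximation
    delta = 23.45 deg * sin(2*pi*(284 + doy)/365) and
    theta = |latitude - delta|, clipped just below pi/2.
    """
    lat = np.asarray(latitude_deg, dtype=float)
    doy = np.asarray(doy, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude must lie in [-90, 90] degrees")
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day of year must lie in [1, 366]")
    decl = 23.45 * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    theta = np.deg2rad(np.abs(lat - decl))
    theta = np.minimum(theta, np.pi / 2 - 1e-9)
    return theta[()] if np.ndim(theta) == 0 else theta


def _window_lengths(year_length: int) -> np.ndarray:
    """Days in each composite window for a year of ``year_length`` days."""
    starts = COMPOSITE_START_DOY
    ends = np.append(starts[1:] - 1, year_length)
    return ends - starts + 1


def composite_8day(values, doy, good, year_length: int = 365):
    """Average good-quality daily values onto the fixed 8-day grid.

    Parameters
    ----------
    values : ndarray, shape (..., n_days)
        Daily values, time on the last axis. NaN = missing.
    doy : ndarray, shape (n_days,)
        1-based day-of-year of each sample (one calendar year).
    good : ndarray of bool, shape broadcastable to ``values``
        Quality flag; only good observations enter a composite.
    year_length : int
        365 (default) or 366.

    Returns
    -------
    composites : ndarray, shape (..., 46)
        Mean of good daily values per window; all-poor/empty windows NaN.
    weights : ndarray, shape (..., 46)
        n_good / window_length per window (0 for empty windows).
    """
    values = np.asarray(values, dtype=float)
    doy = np.asarray(doy)
    good = np.broadcast_to(np.asarray(good, dtype=bool), values.shape)
    if doy.shape[0] != values.shape[-1]:
        raise ValueError("doy length must match the time axis of values")
    win = np.minimum((doy - 1) // 8, N_COMPOSITES - 1).astype(int)
    lengths = _window_lengths(year_length)

    usable = good & np.isfinite(values)
    shape = values.shape[:-1] + (N_COMPOSITES,)
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    vals = np.where(usable, values, 0.0)
    for w in range(N_COMPOSITES):
        m = win == w
        if not m.any():
            continue
        sums[..., w] = vals[..., m].sum(axis=-1)
        counts[..., w] = usable[..., m].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        composites = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    weights = counts / lengths
    return composites, weights


def fill_leading_gap(series):
    """Fill missing leading composites of the first year with climatology.

    ``series`` has shape (n_years, 46, ...). Each missing composite position
    in the *leading* gap of year 0 (positions before its first valid
    composite) is replaced by the mean of that position over years 1..n-1.
    Mirrors the treatment of a sensor record that starts mid-winter, where
    the first weeks are substituted by the multi-year average of the same
    calendar window.

    Returns ``(filled, filled_mask)``; positions that could not be filled
    (all later years missing too) stay NaN and trigger a warning.
    """
    series = np.asarray(series, dtype=float)
    filled = series.copy()
    mask = np.zeros(series.shape, dtype=bool)
    if series.shape[0] < 2:
        return filled, mask
    first = series[0]
    valid = np.isfinite(first)
    # leading gap per trailing-index pixel: positions before first valid
    any_valid = valid.any(axis=0)
    first_valid = np.where(any_valid, valid.argmax(axis=0), series.shape[1])
    pos = np.arange(series.shape[1]).reshape((-1,) + (1,) * (series.ndim - 2))
    leading = pos < first_valid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        clim = np.nanmean(series[1:], axis=0)
    can_fill = leading & ~valid & np.isfinite(clim)
    filled[0][can_fill] = clim[can_fill]
    mask[0] = can_fill
    unfilled = leading & ~valid & ~np.isfinite(clim)
    if unfilled.any():
        warnings.warn(
            "leading-gap positions missing in all later years remain missing",
            stacklevel=2,
        )
    return filled, mask


def per_pixel_max_dvi(dvi_composites, DVIs: float = 0.09, margin: float = 1e-6,
                      axis=0):
    """Canopy maximum DVI per pixel: record maximum of the composite series.

    The maximum is taken over every non-missing composite along ``axis``
    (an int or tuple of ints; default the leading time axis). Pixels whose
    maximum does not exceed DVIs + margin (or that are all-missing) carry no
    vegetation signal: they come back NaN and must stay masked from PPI and
    all downstream phenology.
    """
    d = np.asarray(dvi_composites, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        M = np.nanmax(d, axis=axis)
    M = np.where(np.isfinite(M) & (M > DVIs + margin), M, np.nan)
    return M[()] if np.ndim(M) == 0 else M
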
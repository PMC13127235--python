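"""Seasonal curve fitting for vegetation-index time series.

Two-stage reconstruction, in the style of phenology toolchains built around
TIMESAT-like upper-envelope logic:

1. *Rough fit* — weighted harmonic (Fourier) regression with a 365-day base
   period, iterated with an upper-envelope weight update so that negatively
   biased observations (residual cloud, snow) progressively lose influence.
   The rough curve only serves to locate and delimit growing seasons.
2. *Fine fit* — the Beck double logistic
   ``v(t) = mn + (mx - mn) * (s(rsp*(t - sos)) + s(-rau*(t - eos)) - 1)``
   (``s`` the standard logistic) fitted per season by bounded weighted
   least squares with an analytic Jacobian, again followed by envelope
   re-weighting cycles. Its evaluation provides the daily curve and the
   exact derivative the Gu metric extraction needs.

Everything is deterministic: no stochastic optimizer steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HarmonicFit",
    "DoubleLogisticParams",
    "SeasonWindow",
    "BeckFitResult",
    "wtsm_update",
    "whants_fit",
    "divide_seasons",
    "beck_init",
    "beck_fit",
    "beck_eval",
]


# ---------------------------------------------------------------- harmonic

@dataclass
class HarmonicFit:
    """Weighted harmonic regression result.

    ``a0`` is the mean term, ``a[k-1]``/``b[k-1]`` the cosine/sine
    coefficients of harmonic k; ``fitted`` is the model on the input grid
    and ``weights`` the final (envelope-updated) weights.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    period: float
    t: np.ndarray
    fitted: np.ndarray
    weights: np.ndarray = field(repr=False, default=None)

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        out = np.full(t.shape, self.a0, dtype=float)
        for k in range(len(self.a)):
            out += self.a[k] * np.cos((k + 1) * w * t)
            out += self.b[k] * np.sin((k + 1) * w * t)
        return out


def wtsm_update(values, fitted, weights, original_weights=None,
                floor_frac: float = 0.05):
    """Upper-envelope weight update (TIMESAT wTSM-style).

    Observations at or above the fitted curve keep their weight; those below
    it are down-weighted multiplicatively in proportion to the normalized
    magnitude of their negative residual,

        w_new = original * max(floor_frac, 1 - |r| / (3 * SD(r)))

    where SD(r) is the residual standard deviation over positive-weight
    points. A point three residual-SDs below the curve hits the floor
    (``floor_frac`` of its original weight). Weights never increase above
    the original, and zero-weight points stay zero.
    """
    values = np.asarray(values, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    weights = np.asarray(weights, dtype=float)
    orig = weights if original_weights is None else np.asarray(
        original_weights, dtype=float)

    r = values - fitted
    active = (weights > 0) & np.isfinite(r)
    if active.sum() >= 2:
        sd = float(np.std(r[active]))
    else:
        sd = 0.0
    if sd <= 0:
        return weights.copy()
    factor = np.clip(1.0 - np.abs(r) / (3.0 * sd), floor_frac, 1.0)
    below = active & (r < 0)
    new = weights.copy()
    new[below] = np.minimum(weights[below], orig[below] * factor[below])
    return new


def whants_fit(t, values, weights=None, n_harmonics: int = 3,
               n_outer_iter: int = 3, period: float = 365.0) -> HarmonicFit:
    """Weighted harmonic regression with envelope iterations (wHANTS-style).

    Fits ``a0 + sum_k a_k cos(2 pi k t / period) + b_k sin(...)`` by weighted
    least squares, then repeats after an upper-envelope weight update,
    ``n_outer_iter`` fits in total. Missing values get weight 0.

    Raises ``ValueError`` when fewer than ``2*n_harmonics + 1`` points carry
    positive weight (rank-deficient design).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(values, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float).copy()
    w = np.where(np.isfinite(y), w, 0.0)
    y_safe = np.where(np.isfinite(y), y, 0.0)

    n_par = 2 * n_harmonics + 1
    if int((w > 0).sum()) < n_par:
        raise ValueError(
            f"harmonic fit needs >= {n_par} weighted points, "
            f"got {int((w > 0).sum())}"
        )

    omega = 2.0 * np.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(k * omega * t))
        cols.append(np.sin(k * omega * t))
    X = np.column_stack(cols)

    orig_w = w.copy()
    coef = None
    for it in range(max(1, n_outer_iter)):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y_safe * sw, rcond=None)
        fitted = X @ coef
        if it < n_outer_iter - 1:
            w = wtsm_update(y_safe, fitted, w, original_weights=orig_w)

    a = coef[1::2]
    b = coef[2::2]
    return HarmonicFit(a0=float(coef[0]), a=a, b=b, period=period, t=t,
                       fitted=X @ coef, weights=w)


# ----------------------------------------------------------- season split

@dataclass
class SeasonWindow:
    """One growing season: [t_start, t_end] around peak_doy (absolute days)."""

    year: int
    t_start: float
    t_end: float
    peak_doy: float


def divide_seasons(rough: HarmonicFit, year_start: float, year_end: float,
                   year: int = 0, margin: float = 90.0,
                   min_amplitude: float = 0.05) -> SeasonWindow | None:
    """Locate the single growing season of one calendar year.

    The rough curve is evaluated daily on ``[year_start - margin,
    year_end + margin]``; the peak is the in-year maximum (ties to the
    earliest day) and the window bounds are the curve minima on either side
    of the peak within the margin. Returns ``None`` ("no seasonality") when
    the rough amplitude over the evaluation span is below ``min_amplitude``.
    """
    grid = np.arange(year_start - margin, year_end + margin + 1.0)
    curve = rough.evaluate(grid)
    if np.ptp(curve) < min_amplitude:
        return None
    in_year = (grid >= year_start) & (grid <= year_end)
    peak_idx = int(np.flatnonzero(in_year)[np.argmax(curve[in_year])])
    peak = float(grid[peak_idx])
    left = curve[: peak_idx + 1]
    right = curve[peak_idx:]
    t_start = float(grid[int(np.argmin(left))])
    t_end = float(grid[peak_idx + int(np.argmin(right))])
    return SeasonWindow(year=year, t_start=t_start, t_end=t_end, peak_doy=peak)


# ----------------------------------------------------------------- beck

@dataclass
class DoubleLogisticParams:
    """Beck double-logistic parameters (VI units and day-of-year)."""

    mn: float
    mx: float
    sos: float
    rsp: float
    eos: float
    rau: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mn, self.mx, self.sos, self.rsp,
                         self.eos, self.rau], dtype=float)

    @classmethod
    def from_array(cls, p) -> "DoubleLogisticParams":
        return cls(*(float(v) for v in p))


@dataclass
class BeckFitResult:
    params: DoubleLogisticParams
    rmse: float
    converged: bool
    n_used: int


def _sigmoid(x):
    # exp argument clipped: tails are exactly 0/1 at double precision anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


def beck_eval(params: DoubleLogisticParams, t):
    """Beck curve value and exact first derivative at times ``t``.

    The rise term contributes ``(mx - mn) * rsp / 4`` to the derivative at
    ``t = sos`` (and analogously the decay term at ``eos``).
    """
    t = np.asarray(t, dtype=float)
    mn, mx, sos, rsp, eos, rau = params.as_array()
    amp = mx - mn
    s1 = _sigmoid(rsp * (t - sos))
    s2 = _sigmoid(-rau * (t - eos))
    value = mn + amp * (s1 + s2 - 1.0)
    deriv = amp * (rsp * s1 * (1.0 - s1) - rau * s2 * (1.0 - s2))
    return value, deriv


def _beck_model(p, t):
    s1 = _sigmoid(p[3] * (t - p[2]))
    s2 = _sigmoid(-p[5] * (t - p[4]))
    return p[0] + (p[1] - p[0]) * (s1 + s2 - 1.0)


def _beck_jac(p, t, sw):
    mn, mx, sos, rsp, eos, rau = p
    amp = mx - mn
    s1 = _sigmoid(rsp * (t - sos))
    s2 = _sigmoid(-rau * (t - eos))
    d1 = s1 * (1.0 - s1)
    d2 = s2 * (1.0 - s2)
    J = np.empty((t.size, 6))
    core = s1 + s2 - 1.0
    J[:, 0] = 1.0 - core
    J[:, 1] = core
    J[:, 2] = -amp * rsp * d1
    J[:, 3] = amp * (t - sos) * d1
    J[:, 4] = amp * rau * d2
    J[:, 5] = -amp * (t - eos) * d2
    return J * sw[:, None]


def beck_init(t, values, peak_doy=None) -> DoubleLogisticParams:
    """Initial Beck parameters from the data of one season window.

    mn/mx from the 5th/95th percentiles; sos/eos from the first/last
    half-amplitude crossings on either side of the peak (linear
    interpolation between samples); rates from the window span. When no
    crossing exists (e.g. a monotone ramp) the window quartile days are
    used instead, with a warning.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("season window needs >= 10 points to initialize")
    t, y = t[ok], y[ok]
    order = np.argsort(t)
    t, y = t[order], y[order]

    mn = float(np.percentile(y, 5))
    mx = float(np.percentile(y, 95))
    half = 0.5 * (mn + mx)
    ip = int(np.argmax(y)) if peak_doy is None else int(
        np.argmin(np.abs(t - peak_doy)))

    def _cross(tt, yy, rising):
        above = yy >= half
        idx = np.flatnonzero(above[1:] != above[:-1])
        if idx.size == 0:
            return None
        i = idx[0] if rising else idx[-1]
        y0, y1 = yy[i], yy[i + 1]
        if y1 == y0:
            return float(tt[i])
        frac = (half - y0) / (y1 - y0)
        return float(tt[i] + frac * (tt[i + 1] - tt[i]))

    sos = _cross(t[: ip + 1], y[: ip + 1], rising=True)
    eos = _cross(t[ip:], y[ip:], rising=False)
    if sos is None or eos is None or not sos < eos:
        warnings.warn("half-amplitude crossings not found; "
                      "falling back to window quartiles", stacklevel=2)
        span = t[-1] - t[0]
        sos = float(t[0] + 0.25 * span)
        eos = float(t[0] + 0.75 * span)
    rate = 4.0 / max(0.25 * (eos - sos), 4.0)
    rate = float(np.clip(rate, 0.01, 1.0))
    return DoubleLogisticParams(mn=mn, mx=mx, sos=sos, rsp=rate,
                                eos=eos, rau=rate)


def beck_fit(t, values, weights=None, init: DoubleLogisticParams | None = None,
             window=None, envelope_iters: int = 1, max_nfev: int = 200,
             xtol: float = 1e-8) -> BeckFitResult:
    """Weighted bounded least-squares fit of the Beck double logistic.

    Bounds: mn/mx within the data range widened by 20 % of the amplitude;
    sos/eos within the season window (+/- 30 days); rates in (0.001, 2].
    After convergence, ``envelope_iters`` upper-envelope reweight/refit
    cycles are applied. Non-convergence returns the best parameters found
    with ``converged=False`` rather than raising.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(values, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float).copy()
    w = np.where(np.isfinite(y), w, 0.0)
    use = w > 0
    n_used = int(use.sum())
    if n_used < 7:
        raise ValueError(f"Beck fit needs >= 7 weighted points, got {n_used}")
    tt, yy, ww = t[use], y[use], w[use]

    if init is None:
        init = beck_init(tt, yy)
    if window is None:
        lo_t, hi_t = tt.min() - 30.0, tt.max() + 30.0
    else:
        lo_t, hi_t = window[0] - 30.0, window[1] + 30.0
    ymin, ymax = float(yy.min()), float(yy.max())
    amp = max(ymax - ymin, 1e-6)
    lo = np.array([ymin - 0.2 * amp, ymin, lo_t, 1e-3, lo_t, 1e-3])
    hi = np.array([ymax, ymax + 0.2 * amp, hi_t, 2.0, hi_t, 2.0])
    p0 = np.clip(init.as_array(), lo + 1e-9, hi - 1e-9)

    orig_w = ww.copy()
    converged = True
    p = p0
    for cycle in range(1 + max(0, envelope_iters)):
        sw = np.sqrt(ww)
        res = least_squares(
            lambda q: (_beck_model(q, tt) - yy) * sw,
            p, jac=lambda q: _beck_jac(q, tt, sw),
            bounds=(lo, hi), xtol=xtol, ftol=1e-10, gtol=1e-10,
            max_nfev=max_nfev, method="trf",
        )
        p = res.x
        converged = converged and res.status > 0
        if cycle < envelope_iters:
            ww = wtsm_update(yy, _beck_model(p, tt), ww,
                             original_weights=orig_w)

    fitted = _beck_model(p, tt)
    wr = np.sqrt(np.sum(ww * (fitted - yy) ** 2) / np.sum(ww))
    return BeckFitResult(params=DoubleLogisticParams.from_array(p),
                         rmse=float(wr), converged=bool(converged),
                         n_used=n_used)
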
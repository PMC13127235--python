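"""Gu-method phenological metrics from a fitted daily curve.

The Gu approach characterizes a growing season by tangent-line geometry on
the reconstructed daily VI curve: the *recovery line* is the tangent at the
point of fastest increase, the *senescence line* the tangent at the point
of fastest decrease; the *baseline* and *maxline* are the curve minimum and
maximum; and the *plateau line* is a least-squares line through the curve
between SD and DD0, capturing mid-season greendown. Five dates follow from
analytic line intersections:

======  =============================  ===========================
metric  meaning                        intersection
======  =============================  ===========================
UD      upturn date                    recovery line x baseline
SD      stabilization date             recovery line x maxline
DD0     initial downturn date          senescence line x maxline
DD      downturn date (adjusted)       senescence line x plateau line
RD      recession date                 senescence line x baseline
======  =============================  ===========================

For a pure Beck curve with well-separated flanks the closed forms are
UD = sos - 2/rsp, SD = sos + 2/rsp, DD0 = eos - 2/rau, RD = eos + 2/rau,
and DD = DD0 when the plateau is flat — the independent oracle used in
tests.

Metrics are real-valued days (rounding, if any, happens at output time)
and are equivariant under time shifts and invariant under positive affine
transforms of the VI axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import DoubleLogisticParams, beck_eval

__all__ = [
    "GuLines",
    "PhenoMetrics",
    "build_gu_lines",
    "extract_gu_metrics",
    "gu_closed_form",
]

_PARALLEL_TOL = 1e-9


@dataclass
class GuLines:
    """Tangent/boundary lines of one season (lines as (slope, intercept))."""

    baseline: float
    maxline: float
    recovery: tuple[float, float]
    recovery_doy: float
    senescence: tuple[float, float]
    senescence_doy: float
    plateau: tuple[float, float]
    valid: bool = True


@dataclass
class PhenoMetrics:
    """The five Gu dates (day units; NaN where invalid) plus validity flags."""

    ud: float = np.nan
    sd: float = np.nan
    dd0: float = np.nan
    dd: float = np.nan
    rd: float = np.nan
    valid: dict = None

    def __post_init__(self):
        if self.valid is None:
            self.valid = {k: np.isfinite(getattr(self, k))
                          for k in ("ud", "sd", "dd0", "dd", "rd")}

    def as_tuple(self):
        return (self.ud, self.sd, self.dd0, self.dd, self.rd)


def _intersect_level(line, level):
    slope, intercept = line
    return (level - intercept) / slope


def build_gu_lines(t, curve, deriv, plateau_from_curve: bool = True) -> GuLines:
    """Construct the Gu lines from a daily curve and its derivative.

    Tangent points: maximum derivative at or before the curve peak
    (recovery) and minimum derivative at or after it (senescence); ties
    break to the earliest day. A window with no positive maximum derivative
    or no negative minimum derivative (monotone curve) yields
    ``valid=False`` — no exception.

    The plateau line is the OLS line through ``(t, curve)`` for t in
    [SD, DD0]; when that interval holds fewer than 2 samples the plateau
    degenerates to the flat maxline (so DD = DD0).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(curve, dtype=float)
    dy = np.asarray(deriv, dtype=float)

    baseline = float(np.min(y))
    maxline = float(np.max(y))
    ip = int(np.argmax(y))  # argmax -> earliest maximal sample

    invalid = GuLines(baseline, maxline, (np.nan, np.nan), np.nan,
                      (np.nan, np.nan), np.nan, (np.nan, np.nan), valid=False)
    if ip == 0 or ip == len(t) - 1:
        return invalid
    ir = int(np.argmax(dy[: ip + 1]))
    isn = ip + int(np.argmin(dy[ip:]))
    if not (dy[ir] > 0 and dy[isn] < 0):
        return invalid

    rec = (float(dy[ir]), float(y[ir] - dy[ir] * t[ir]))
    sen = (float(dy[isn]), float(y[isn] - dy[isn] * t[isn]))

    sd = _intersect_level(rec, maxline)
    dd0 = _intersect_level(sen, maxline)
    sel = (t >= sd) & (t <= dd0)
    if plateau_from_curve and sel.sum() >= 2 and dd0 > sd:
        slope, intercept = np.polyfit(t[sel], y[sel], 1)
        plateau = (float(slope), float(intercept))
    else:
        plateau = (0.0, maxline)

    return GuLines(baseline=baseline, maxline=maxline,
                   recovery=rec, recovery_doy=float(t[ir]),
                   senescence=sen, senescence_doy=float(t[isn]),
                   plateau=plateau, valid=True)


def extract_gu_metrics(lines: GuLines, window=None,
                       window_slack: float = 60.0) -> PhenoMetrics:
    """Solve the Gu line intersections analytically.

    DD comes from senescence x plateau and is only meaningful when the two
    are not parallel (slope difference above 1e-9); a parallel plateau
    invalidates DD alone. Metrics falling outside ``window`` +/- slack are
    flagged invalid. Validity of the full set additionally requires the
    ordering UD < SD < DD0 < RD.
    """
    if not lines.valid:
        return PhenoMetrics()

    ud = _intersect_level(lines.recovery, lines.baseline)
    sd = _intersect_level(lines.recovery, lines.maxline)
    dd0 = _intersect_level(lines.senescence, lines.maxline)
    rd = _intersect_level(lines.senescence, lines.baseline)

    s_sen, b_sen = lines.senescence
    s_pla, b_pla = lines.plateau
    if abs(s_sen - s_pla) < _PARALLEL_TOL:
        dd = np.nan
    else:
        dd = (b_pla - b_sen) / (s_sen - s_pla)

    metrics = {"ud": ud, "sd": sd, "dd0": dd0, "dd": dd, "rd": rd}
    valid = {k: np.isfinite(v) for k, v in metrics.items()}
    if window is not None:
        lo = window[0] - window_slack
        hi = window[1] + window_slack
        for k, v in metrics.items():
            if valid[k] and not (lo <= v <= hi):
                valid[k] = False
    if all(valid[k] for k in ("ud", "sd", "dd0", "rd")):
        if not (ud < sd < dd0 < rd):
            for k in ("ud", "sd", "dd0", "rd"):
                valid[k] = False
    out = {k: (v if valid[k] else np.nan) for k, v in metrics.items()}
    return PhenoMetrics(**out, valid=valid)


def gu_closed_form(params: DoubleLogisticParams,
                   separation_margin: float = 10.0) -> PhenoMetrics:
    """Closed-form Gu metrics of a pure Beck curve (test oracle).

    Valid only for well-separated flanks, eos - sos > 2/rsp + 2/rau +
    margin, where the two logistic terms decouple: the recovery tangent
    sits at sos with slope (mx-mn)*rsp/4 through ((mn+mx)/2), giving
    UD = sos - 2/rsp and SD = sos + 2/rsp (senescence analogously), and a
    flat plateau gives DD = DD0.
    """
    sep = params.eos - params.sos
    if not sep > 2.0 / params.rsp + 2.0 / params.rau + separation_margin:
        raise ValueError("closed form requires well-separated seasons")
    ud = params.sos - 2.0 / params.rsp
    sd = params.sos + 2.0 / params.rsp
    dd0 = params.eos - 2.0 / params.rau
    rd = params.eos + 2.0 / params.rau
    return PhenoMetrics(ud=ud, sd=sd, dd0=dd0, dd=dd0, rd=rd)


def metrics_from_params(params: DoubleLogisticParams, window,
                        step: float = 1.0) -> PhenoMetrics:
    """Numerical Gu extraction for a fitted Beck season.

    Evaluates the curve and analytic derivative on integer days across the
    window and runs the tangent-line geometry.
    """
    t = np.arange(window[0], window[1] + step / 2, step)
    value, deriv = beck_eval(params, t)
    lines = build_gu_lines(t, value, deriv)
    return extract_gu_metrics(lines, window=window)
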
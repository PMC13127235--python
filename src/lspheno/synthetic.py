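"""Synthetic reflectance scenes with known phenological ground truth.

Every downstream stage of the package (index computation, compositing,
curve fitting, Gu extraction, trend mapping, VI-vs-GPP statistics) is
testable by parameter recovery against scenes produced here, without any
satellite download.

The generative model, per pixel and calendar year:

1. A daily leaf-area-index trajectory follows the Beck double logistic in
   LAI space (baseline ``mn_lai``, peak ``mx_lai``, spring/autumn
   inflections ``sos``/``eos`` with rates ``rsp``/``rau``), optionally with
   a linear greendown ``plateau_slope`` across the peak plateau. Spatial
   fields carry smooth gradients; interannual change applies prescribed
   linear trends (days per year) plus zero-mean jitter.
2. Reflectance follows an inverted Beer's-law canopy model:
   ``DVI = M_true - (M_true - DVIs_true) * exp(-c_lai2dvi * LAI)``, with
   red and blue at constant soil/background levels; additive Gaussian
   noise per band.
3. Contamination: cloudy days depress DVI (NIR down, red up) and are
   QA-flagged with 90 % probability — the remainder escape QA, which is
   what upper-envelope fitting has to absorb; winter snow episodes raise
   visible reflectance and collapse DVI toward zero.
4. GPP/SIF proxies: ``GPP = lue * (1 - exp(-0.5*LAI)) * S(t)`` where the
   seasonal scalar S starts its logistic decline ``autumn_lead_days``
   before the structural (LAI) autumn inflection — photosynthesis wanes
   before greenness does; SIF is proportional to GPP plus noise.

Default parameter values emulate a semi-arid temperate grassland scene
(moderate LAI amplitude, bright soil); docs/methods.md discusses each
choice and its units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr


__all__ = [
    "TruthParams",
    "Optics",
    "Contamination",
    "SifGppConfig",
    "SceneConfig",
    "SyntheticScene",
    "make_truth",
    "lai_series",
    "reflectance_from_lai",
    "contaminate",
    "simulate_sif_gpp",
    "generate_scene",
]

DAYS_PER_YEAR = 365
DOY = np.arange(1, DAYS_PER_YEAR + 1)


@dataclass
class TruthParams:
    """Ground-truth seasonal parameters of one pixel.

    Units: LAI in m2/m2, dates in day-of-year, rates in 1/day, trends in
    days/year, ``plateau_slope`` in LAI/day (<= 0, greendown).
    """

    mn_lai: float = 0.2
    mx_lai: float = 1.2
    sos: float = 130.0
    rsp: float = 0.2
    eos: float = 280.0
    rau: float = 0.2
    plateau_slope: float = 0.0
    sos_trend: float = 0.0
    eos_trend: float = 0.0

    def validate(self) -> None:
        if not (self.mx_lai > self.mn_lai >= 0):
            raise ValueError("need mx_lai > mn_lai >= 0")
        if self.rsp <= 0 or self.rau <= 0:
            raise ValueError("rates must be positive")
        if not (0 < self.sos < self.eos < 366):
            raise ValueError("need 0 < sos < eos < 366")
        if not (self.eos - self.sos) > 2.0 / self.rsp + 2.0 / self.rau:
            raise ValueError("seasons not well separated: "
                             "(eos - sos) must exceed 2/rsp + 2/rau")
        if self.plateau_slope > 0:
            raise ValueError("plateau_slope must be <= 0")


@dataclass
class Optics:
    """LAI-to-reflectance coupling (Beer's-law canopy model)."""

    M_true: float = 0.7        # asymptotic closed-canopy DVI
    DVIs_true: float = 0.09    # bare-soil DVI
    c_lai2dvi: float = 0.6     # extinction coefficient (1/LAI)
    red_base: float = 0.12     # soil red reflectance
    blue_base: float = 0.06    # soil blue reflectance

    def validate(self) -> None:
        if not (self.DVIs_true < self.M_true < 1.0):
            raise ValueError("need DVIs_true < M_true < 1")
        if self.c_lai2dvi <= 0:
            raise ValueError("c_lai2dvi must be positive")


@dataclass
class Contamination:
    """Noise, cloud, and snow model."""

    noise_sd: float = 0.02          # per-band additive Gaussian sd
    cloud_prob: float = 0.2         # Bernoulli per pixel-day
    cloud_vi_bias: float = -0.15    # mean DVI depression on cloud days (<0)
    cloud_qa_detect: float = 0.9    # P(QA flags a cloudy day)
    snow_window: tuple = (335, 60)  # DOY range, wrapping over new year
    snow_prob: float = 0.08         # Bernoulli per pixel-day inside window
    snow_qa_miss_prob: float = 0.1  # P(snow day escapes QA)

    def validate(self) -> None:
        for name in ("cloud_prob", "cloud_qa_detect", "snow_prob",
                     "snow_qa_miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cloud_vi_bias > 0:
            raise ValueError("cloud_vi_bias must be <= 0 (clouds depress VI)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SifGppConfig:
    """GPP/SIF proxy model.

    ``lue`` scales peak GPP (g C m-2 day-1); ``autumn_lead_days`` is how
    many days the photosynthetic autumn decline precedes the structural
    one; ``sif_scale`` converts GPP to SIF units; ``noise_sd`` is the SIF
    noise sd expressed as a fraction of peak SIF.
    """

    lue: float = 6.0
    autumn_lead_days: float = 20.0
    sif_scale: float = 0.02
    noise_sd: float = 0.05

    def validate(self) -> None:
        if self.autumn_lead_days < 0:
            raise ValueError("autumn_lead_days must be >= 0")
        if self.lue < 0 or self.sif_scale < 0 or self.noise_sd < 0:
            raise ValueError("lue, sif_scale, noise_sd must be >= 0")


@dataclass
class SceneConfig:
    """Full configuration of a synthetic scene."""

    ny: int = 8
    nx: int = 8
    years: tuple = (2000,)
    base_truth: TruthParams = field(default_factory=TruthParams)
    sos_gradient: float = 6.0   # edge-to-edge spatial range, days
    eos_gradient: float = 6.0
    mx_gradient: float = 0.2    # edge-to-edge range of mx_lai
    jitter_sd: float = 2.0      # interannual sos/eos jitter, days
    lat_range: tuple = (38.0, 34.0)  # north row first
    optics: Optics = field(default_factory=Optics)
    contamination: Contamination = field(default_factory=Contamination)
    sif_gpp: SifGppConfig = field(default_factory=SifGppConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.ny < 1 or self.nx < 1:
            raise ValueError("grid must contain at least one pixel")
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        self.base_truth.validate()
        self.optics.validate()
        self.contamination.validate()
        self.sif_gpp.validate()


@dataclass
class SyntheticScene:
    """A generated scene: reflectance + QA, truth, proxies, true metrics."""

    reflectance: xr.Dataset
    truth: xr.Dataset
    sif: xr.DataArray
    gpp: xr.DataArray
    true_metrics: xr.Dataset
    config: SceneConfig


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _plane(ny: int, nx: int) -> np.ndarray:
    """Smooth diagonal gradient field in [-0.5, 0.5]."""
    ry = np.linspace(0.0, 1.0, ny)[:, None] if ny > 1 else np.zeros((1, 1))
    rx = np.linspace(0.0, 1.0, nx)[None, :] if nx > 1 else np.zeros((1, 1))
    return (ry + rx) / 2.0 - 0.5 * (float(ny > 1) + float(nx > 1)) / 2.0


def make_truth(config: SceneConfig, rng=None) -> xr.Dataset:
    """Per-pixel, per-year truth parameters with gradients, trends, jitter.

    Reproducible: the jitter stream derives from ``config.seed`` alone.
    Raises when a grid is degenerate or a trend drives ``eos <= sos``
    anywhere (the offending pixel-year is named).
    """
    config.validate()
    if rng is None:
        rng = _rngs(config.seed, 4)[0]
    ny, nx = config.ny, config.nx
    years = np.asarray(config.years)
    n_years = len(years)
    bt = config.base_truth
    g = _plane(ny, nx)

    sos0 = bt.sos + config.sos_gradient * g
    eos0 = bt.eos + config.eos_gradient * g
    mx0 = bt.mx_lai + config.mx_gradient * g

    shape = (n_years, ny, nx)
    dy = (years - years[0]).astype(float)[:, None, None]
    sos = sos0[None] + bt.sos_trend * dy
    eos = eos0[None] + bt.eos_trend * dy
    if config.jitter_sd > 0:
        sos = sos + rng.normal(0.0, config.jitter_sd, size=shape)
        eos = eos + rng.normal(0.0, config.jitter_sd, size=shape)

    sep_min = 2.0 / bt.rsp + 2.0 / bt.rau
    bad = eos - sos <= sep_min
    if bad.any():
        iy, r, c = (int(v) for v in np.argwhere(bad)[0])
        raise ValueError(
            f"trend/jitter produced an invalid season (eos <= sos + "
            f"separation) at pixel (row={r}, col={c}), year {years[iy]}"
        )

    const = np.ones(shape)
    ds = xr.Dataset(
        {
            "mn_lai": (("year", "y", "x"), const * bt.mn_lai),
            "mx_lai": (("year", "y", "x"), np.broadcast_to(mx0, shape).copy()),
            "sos": (("year", "y", "x"), sos),
            "rsp": (("year", "y", "x"), const * bt.rsp),
            "eos": (("year", "y", "x"), eos),
            "rau": (("year", "y", "x"), const * bt.rau),
            "plateau_slope": (("year", "y", "x"), const * bt.plateau_slope),
        },
        coords={"year": years, "y": np.arange(ny), "x": np.arange(nx)},
    )
    return ds


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


def lai_series(truth: TruthParams, dates) -> np.ndarray:
    """Daily LAI trajectory of one pixel (Beck form plus optional greendown).

    ``LAI(t) = mn + (mx - mn) * (s(rsp*(t - sos)) + s(-rau*(t - eos)) - 1)``
    with the plateau term ``plateau_slope * (t - sos - 2/rsp)`` added only
    inside ``(sos + 2/rsp, eos - 2/rau)`` and the result clipped at mn.
    """
    t = np.asarray(dates, dtype=float)
    return _lai_fields(t, truth.mn_lai, truth.mx_lai, truth.sos, truth.rsp,
                       truth.eos, truth.rau, truth.plateau_slope)


def _lai_fields(t, mn, mx, sos, rsp, eos, rau, plateau_slope):
    """Vectorized LAI for scalar-or-grid parameters; t broadcasts in front."""
    expand = (np.ndim(mn) > 0) or (np.ndim(sos) > 0)
    if expand:
        t = np.asarray(t, dtype=float).reshape((-1,) + (1,) * np.ndim(sos))
    lai = mn + (mx - mn) * (_logistic(rsp * (t - sos))
                            + _logistic(-rau * (t - eos)) - 1.0)
    on = (t > sos + 2.0 / rsp) & (t < eos - 2.0 / rau)
    lai = lai + np.where(on, plateau_slope * (t - sos - 2.0 / rsp), 0.0)
    return np.maximum(lai, mn)


def reflectance_from_lai(lai, optics: Optics, noise_sd: float = 0.0,
                         rng=None):
    """Blue/red/NIR reflectance (plus the clean DVI) from an LAI field.

    ``DVI = M_true - (M_true - DVIs_true) * exp(-c_lai2dvi * LAI)``;
    red and blue sit at the soil baselines; NIR = red + DVI. Additive
    zero-mean Gaussian noise of ``noise_sd`` per band; all bands clipped
    to [0, 1].
    """
    optics.validate()
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    dvi = optics.M_true - (optics.M_true - optics.DVIs_true) * np.exp(
        -optics.c_lai2dvi * lai)
    assert np.all(dvi < optics.M_true)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        red = optics.red_base + rng.normal(0.0, noise_sd, lai.shape)
        nir = red + dvi + rng.normal(0.0, noise_sd, lai.shape)
        blue = optics.blue_base + rng.normal(0.0, noise_sd, lai.shape)
    else:
        red = np.full(lai.shape, optics.red_base)
        nir = red + dvi
        blue = np.full(lai.shape, optics.blue_base)
    clip = lambda a: np.clip(a, 0.0, 1.0)
    return clip(blue), clip(red), clip(nir), dvi


def _in_snow_window(doy, window):
    lo, hi = window
    doy = np.asarray(doy)
    if lo <= hi:
        return (doy >= lo) & (doy <= hi)
    return (doy >= lo) | (doy <= hi)


def contaminate(reflectance: xr.Dataset, config: SceneConfig,
                rng=None) -> xr.Dataset:
    """Apply cloud and snow contamination plus QA flags to a clean scene.

    Cloudy pixel-days lose DVI (NIR down 60 %, red up 40 % of a draw around
    ``|cloud_vi_bias|``) and are QA-flagged poor with probability
    ``cloud_qa_detect``. Snow days inside the snow window brighten the
    visible bands toward 0.7 and collapse DVI to ~0; they are flagged poor
    except with probability ``snow_qa_miss_prob``. Only contaminated
    observations are ever flagged poor.
    """
    con = config.contamination
    con.validate()
    if rng is None:
        rng = _rngs(config.seed, 4)[2]
    out = reflectance.copy(deep=True)
    nir = out["nir"].values
    red = out["red"].values
    blue = out["blue"].values
    good = out["qa"].values.astype(bool)
    doy = out["doy"].values
    shape = nir.shape  # (time, y, x)

    if con.cloud_prob > 0 and con.cloud_vi_bias < 0:
        cloudy = rng.random(shape) < con.cloud_prob
        depth = np.abs(con.cloud_vi_bias) * rng.uniform(0.5, 1.5, shape)
        nir = np.where(cloudy, nir - 0.6 * depth, nir)
        red = np.where(cloudy, red + 0.4 * depth, red)
        flagged = cloudy & (rng.random(shape) < con.cloud_qa_detect)
        good = good & ~flagged

    if con.snow_prob > 0:
        in_window = _in_snow_window(doy, con.snow_window)
        snowy = (rng.random(shape) < con.snow_prob) & in_window[:, None, None]
        bright = 0.6 + rng.uniform(0.0, 0.1, shape)
        nir = np.where(snowy, bright + rng.uniform(-0.02, 0.02, shape), nir)
        red = np.where(snowy, bright, red)
        blue = np.where(snowy, 0.95 * bright, blue)
        flagged = snowy & (rng.random(shape) >= con.snow_qa_miss_prob)
        good = good & ~flagged

    out["nir"].values = np.clip(nir, 0.0, 1.0)
    out["red"].values = np.clip(red, 0.0, 1.0)
    out["blue"].values = np.clip(blue, 0.0, 1.0)
    out["qa"].values = good.astype(np.int8)
    return out


def simulate_sif_gpp(lai, eos, rau, config: SifGppConfig, doy, sos=None,
                     rng=None):
    """Daily GPP and SIF proxies from the clean LAI trajectory.

    ``GPP = lue * (1 - exp(-0.5*LAI)) * S(t)`` with the seasonal scalar
    ``S = min(1, 2*s(-rau*(t - (eos - autumn_lead_days))))`` — unity until
    the photosynthetic decline starts ``autumn_lead_days`` before the
    structural inflection, then a logistic fall at the autumn rate.
    ``SIF = sif_scale * GPP + noise``, clipped at zero.
    """
    config.validate()
    lai = np.asarray(lai, dtype=float)
    doy = np.asarray(doy, dtype=float)
    t0 = np.asarray(eos, dtype=float) - config.autumn_lead_days
    if sos is not None and np.any(t0 <= np.asarray(sos)):
        raise ValueError("autumn_lead_days moves the GPP decline before sos")
    t = doy.reshape((-1,) + (1,) * (np.ndim(t0)))
    s = np.minimum(1.0, 2.0 * _logistic(-np.asarray(rau) * (t - t0)))
    gpp = config.lue * (1.0 - np.exp(-0.5 * lai)) * s
    if rng is None:
        rng = np.random.default_rng(0)
    peak_sif = config.sif_scale * config.lue
    sif = config.sif_scale * gpp + rng.normal(
        0.0, config.noise_sd * max(peak_sif, 1e-12), gpp.shape)
    return np.maximum(gpp, 0.0), np.maximum(sif, 0.0)


def _true_metrics(truth: xr.Dataset) -> xr.Dataset:
    """Closed-form Gu metrics of the truth grid (vectorized oracle)."""
    sos, rsp = truth["sos"].values, truth["rsp"].values
    eos, rau = truth["eos"].values, truth["rau"].values
    dims = ("year", "y", "x")
    return xr.Dataset(
        {
            "ud": (dims, sos - 2.0 / rsp),
            "sd": (dims, sos + 2.0 / rsp),
            "dd0": (dims, eos - 2.0 / rau),
            "dd": (dims, eos - 2.0 / rau),
            "rd": (dims, eos + 2.0 / rau),
        },
        coords=truth.coords,
    )


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a full synthetic scene from one seed.

    Deterministic per config+seed: truth, band noise, contamination, and
    proxy noise each consume an independent child stream of the seed.
    """
    config.validate()
    rng_truth, rng_noise, rng_contam, rng_sif = _rngs(config.seed, 4)
    truth = make_truth(config, rng=rng_truth)
    ny, nx = config.ny, config.nx
    years = list(config.years)
    n_years = len(years)

    doy_all = np.tile(DOY, n_years)
    year_all = np.repeat(years, DAYS_PER_YEAR)
    t_index = np.arange(n_years * DAYS_PER_YEAR)

    lai = np.empty((n_years * DAYS_PER_YEAR, ny, nx))
    gpp = np.empty_like(lai)
    sif = np.empty_like(lai)
    for i in range(n_years):
        tr = truth.isel(year=i)
        block = slice(i * DAYS_PER_YEAR, (i + 1) * DAYS_PER_YEAR)
        lai[block] = _lai_fields(
            DOY.astype(float), tr["mn_lai"].values, tr["mx_lai"].values,
            tr["sos"].values, tr["rsp"].values, tr["eos"].values,
            tr["rau"].values, tr["plateau_slope"].values)
        gpp[block], sif[block] = simulate_sif_gpp(
            lai[block], tr["eos"].values, tr["rau"].values, config.sif_gpp,
            DOY, sos=tr["sos"].values, rng=rng_sif)

    blue, red, nir, _ = reflectance_from_lai(
        lai, config.optics, noise_sd=config.contamination.noise_sd,
        rng=rng_noise)

    lat = np.linspace(config.lat_range[0], config.lat_range[1], ny) \
        if ny > 1 else np.array([np.mean(config.lat_range)])
    refl = xr.Dataset(
        {
            "blue": (("time", "y", "x"), blue),
            "red": (("time", "y", "x"), red),
            "nir": (("time", "y", "x"), nir),
            "qa": (("time", "y", "x"),
                   np.ones((n_years * DAYS_PER_YEAR, ny, nx), dtype=np.int8)),
        },
        coords={
            "time": t_index,
            "doy": ("time", doy_all),
            "cal_year": ("time", year_all),
            "y": np.arange(ny),
            "x": np.arange(nx),
            "lat": ("y", lat),
        },
        attrs={"qa_convention": "1 = good, 0 = poor",
               "calendar": "365-day (no leap)"},
    )
    refl = contaminate(refl, config, rng=rng_contam)

    dims = ("time", "y", "x")
    return SyntheticScene(
        reflectance=refl,
        truth=truth,
        sif=xr.DataArray(sif, coords=refl["nir"].coords, dims=dims, name="sif"),
        gpp=xr.DataArray(gpp, coords=refl["nir"].coords, dims=dims, name="gpp"),
        true_metrics=_true_metrics(truth),
        config=config,
    )
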
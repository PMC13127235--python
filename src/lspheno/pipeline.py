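"""End-to-end pipeline: reflectance cube -> VI composites -> fitted seasons
-> Gu metrics (-> trends), with a YAML-configurable runner.

The per-pixel chain mirrors the processing applied to satellite records:
quality-filtered 8-day compositing of each index, a weighted-harmonic
rough fit with upper-envelope reweighting to divide growing seasons, a
Beck double-logistic fine fit per season, and tangent-line (Gu) metric
extraction from the reconstructed daily curve.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import xarray as xr
import yaml

from . import indices as vi
from .fitting import beck_fit, beck_init, divide_seasons, whants_fit
from .io import RunManifest, write_metrics_csv, write_scene
from .metrics import metrics_from_params
from .synthetic import DAYS_PER_YEAR, SceneConfig, generate_scene
from .trends import region_summary, trend_map

__all__ = [
    "VIOptions",
    "FitOptions",
    "PipelineConfig",
    "compute_vi_composites",
    "extract_pixel_metrics",
    "extract_metrics_cube",
    "run_pipeline",
    "load_config",
]

METRIC_NAMES = ("ud", "sd", "dd0", "dd", "rd")
DEFAULT_INDICES = ("evi", "kndvi", "ppi")


@dataclass
class VIOptions:
    """Index-computation options (PPI geometry and clamping)."""

    dc: float = 0.0              # diffuse fraction (0 = direct beam)
    theta_mode: str = "noon"     # "noon" (per-row latitude) or "fixed"
    theta_fixed: float = 0.6     # radians, used when theta_mode == "fixed"
    eps: float = 0.04            # PPI saturation clamp, DVI units
    DVIs: float = 0.09
    G: float = 0.5


@dataclass
class FitOptions:
    """Curve-fitting options for the rough and fine stages."""

    n_harmonics: int = 3
    n_outer_iter: int = 3        # wHANTS envelope iterations
    envelope_iters: int = 1      # Beck post-convergence reweight cycles
    min_amplitude: float = 0.05  # "no seasonality" floor, VI units
    season_margin: float = 90.0  # days beyond the calendar year
    max_nfev: int = 200


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-scene pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    indices: tuple = DEFAULT_INDICES
    vi_options: VIOptions = field(default_factory=VIOptions)
    fit_options: FitOptions = field(default_factory=FitOptions)
    write_scene_nc: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _split_years(arr, n_years):
    """(time, y, x) -> (n_years, 365, y, x)."""
    return arr.reshape(n_years, DAYS_PER_YEAR, *arr.shape[1:])


def compute_vi_composites(reflectance: xr.Dataset,
                          index_names=DEFAULT_INDICES,
                          options: VIOptions | None = None) -> dict:
    """Compute 8-day composites of the requested indices from a scene cube.

    Daily index values are computed from the reflectance bands, then good-QA
    days are averaged onto the fixed composite grid per calendar year.
    PPI is derived from the *composited* DVI with the per-pixel record
    maximum as M and the gain K evaluated at each composite mid-date
    (per-row latitude at local solar noon, unless a fixed angle is set).

    Returns a dict with per-index ``(n_years, 46, ny, nx)`` value arrays
    under their names, a shared ``weights`` array, ``years``, ``m_grid``
    (canopy maximum DVI, NaN = non-vegetated), and the composite mid-DOY.
    """
    options = options or VIOptions()
    blue = reflectance["blue"].values
    red = reflectance["red"].values
    nir = reflectance["nir"].values
    good = reflectance["qa"].values.astype(bool)
    doy = reflectance["doy"].values
    years = np.unique(reflectance["cal_year"].values)
    n_years = len(years)
    ny, nx = blue.shape[1], blue.shape[2]

    daily = {}
    if "evi" in index_names:
        daily["evi"] = vi.compute_evi(nir, red, blue)
    if "kndvi" in index_names:
        daily["kndvi"] = vi.compute_kndvi(nir, red)
    daily["dvi"] = vi.compute_dvi(nir, red)

    comp = {}
    weights = None
    one_year_doy = doy[:DAYS_PER_YEAR]
    for name, vals in daily.items():
        vals_y = _split_years(vals, n_years)
        good_y = _split_years(good, n_years)
        out = np.empty((n_years, vi.N_COMPOSITES, ny, nx))
        wts = np.empty_like(out)
        for i in range(n_years):
            v = np.moveaxis(vals_y[i], 0, -1)   # (y, x, 365)
            q = np.moveaxis(good_y[i], 0, -1)
            c, w = vi.composite_8day(v, one_year_doy, q,
                                     year_length=DAYS_PER_YEAR)
            out[i] = np.moveaxis(c, -1, 0)
            wts[i] = np.moveaxis(w, -1, 0)
        comp[name] = out
        weights = wts  # identical across indices (same QA pattern)

    m_grid = vi.per_pixel_max_dvi(comp["dvi"], DVIs=options.DVIs,
                                  axis=(0, 1))
    if "ppi" in index_names:
        mid_doy = vi.COMPOSITE_START_DOY + 3.5
        mid_doy[-1] = vi.COMPOSITE_START_DOY[-1] + 2.0
        if options.theta_mode == "noon":
            lat = (reflectance["lat"].values if "lat" in reflectance.coords
                   else np.full(ny, 36.0))
            theta = vi.solar_zenith_noon(lat[None, :], mid_doy[:, None])
            theta = theta[None, :, :, None]       # (1, 46, ny, 1)
        elif options.theta_mode == "fixed":
            theta = options.theta_fixed
        else:
            raise ValueError(f"unknown theta_mode '{options.theta_mode}'")
        params = vi.PPIParams(M=m_grid, DVIs=options.DVIs, G=options.G,
                              dc=options.dc, theta=theta, eps=options.eps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ppi = vi.compute_ppi(comp["dvi"], params)
        ppi = np.where(np.isfinite(m_grid)[None, None], ppi, np.nan)
        comp["ppi"] = ppi

    return {
        "indices": {k: comp[k] for k in index_names if k in comp},
        "dvi": comp["dvi"],
        "weights": weights,
        "years": years,
        "m_grid": m_grid,
        "mid_doy": vi.COMPOSITE_START_DOY + 3.5,
    }


def extract_pixel_metrics(values, weights, years,
                          fit_options: FitOptions | None = None):
    """Gu metrics for one pixel's multi-year composite series.

    ``values``/``weights`` are (n_years, 46). For each year, the rough
    harmonic fit uses the year's composites plus a neighborhood of the
    adjacent years (up to ~90 days each side); the season window from the
    rough fit delimits the Beck fine fit; metrics come from the fitted
    daily curve. Returns a (n_years, 5) array (UD, SD, DD0, DD, RD as
    day-of-year; NaN = invalid/no seasonality/failed fit).
    """
    fo = fit_options or FitOptions()
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_years = values.shape[0]
    mid = vi.COMPOSITE_START_DOY + 3.5
    mid[-1] = vi.COMPOSITE_START_DOY[-1] + 2.0
    n_nb = int(np.ceil(fo.season_margin / 8.0))  # neighbor composites

    out = np.full((n_years, len(METRIC_NAMES)), np.nan)
    for i in range(n_years):
        t_parts = [i * DAYS_PER_YEAR + mid]
        v_parts = [values[i]]
        w_parts = [weights[i]]
        if i > 0:
            t_parts.insert(0, (i - 1) * DAYS_PER_YEAR + mid[-n_nb:])
            v_parts.insert(0, values[i - 1, -n_nb:])
            w_parts.insert(0, weights[i - 1, -n_nb:])
        if i < n_years - 1:
            t_parts.append((i + 1) * DAYS_PER_YEAR + mid[:n_nb])
            v_parts.append(values[i + 1, :n_nb])
            w_parts.append(weights[i + 1, :n_nb])
        t = np.concatenate(t_parts)
        v = np.concatenate(v_parts)
        w = np.concatenate(w_parts)
        w = np.where(np.isfinite(v), w, 0.0)
        if (w > 0).sum() < 2 * fo.n_harmonics + 1:
            continue
        rough = whants_fit(t, v, w, n_harmonics=fo.n_harmonics,
                           n_outer_iter=fo.n_outer_iter)
        season = divide_seasons(rough, i * DAYS_PER_YEAR + 1,
                                (i + 1) * DAYS_PER_YEAR, year=i,
                                margin=fo.season_margin,
                                min_amplitude=fo.min_amplitude)
        if season is None:
            continue
        sel = (t >= season.t_start) & (t <= season.t_end) & (w > 0)
        if sel.sum() < 7:
            continue
        try:
            init = beck_init(t[sel], v[sel], peak_doy=season.peak_doy)
            fit = beck_fit(t[sel], v[sel], w[sel], init=init,
                           window=(season.t_start, season.t_end),
                           envelope_iters=fo.envelope_iters,
                           max_nfev=fo.max_nfev)
        except ValueError:
            continue
        pm = metrics_from_params(fit.params,
                                 (season.t_start, season.t_end))
        offset = i * DAYS_PER_YEAR
        out[i] = [getattr(pm, m) - offset if np.isfinite(getattr(pm, m))
                  else np.nan for m in METRIC_NAMES]
    return out


def extract_metrics_cube(composites: dict,
                         fit_options: FitOptions | None = None) -> dict:
    """Run the fitting + Gu chain for every pixel and index of a scene.

    ``composites`` is the output of :func:`compute_vi_composites`.
    Returns {index -> {metric -> (n_years, ny, nx) array}}; non-vegetated
    pixels (no canopy-maximum DVI) propagate as all-NaN.
    """
    fo = fit_options or FitOptions()
    weights = composites["weights"]
    m_grid = composites["m_grid"]
    years = composites["years"]
    n_years = len(years)
    ny, nx = weights.shape[2], weights.shape[3]

    result = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, cube in composites["indices"].items():
            per_metric = {m: np.full((n_years, ny, nx), np.nan)
                          for m in METRIC_NAMES}
            for r in range(ny):
                for c in range(nx):
                    if not np.isfinite(m_grid[r, c]):
                        continue
                    pm = extract_pixel_metrics(cube[:, :, r, c],
                                               weights[:, :, r, c],
                                               years, fit_options=fo)
                    for j, m in enumerate(METRIC_NAMES):
                        per_metric[m][:, r, c] = pm[:, j]
            result[name] = per_metric
    return result


def load_config(path: str) -> PipelineConfig:
    """Load a pipeline configuration from YAML (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _config_from_dict(raw)


def _build(cls, raw: dict, path: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    return raw


def _config_from_dict(raw: dict) -> PipelineConfig:
    from .synthetic import Contamination, Optics, SifGppConfig, TruthParams

    raw = dict(raw)
    scene_raw = dict(raw.pop("scene", {}))
    nested = {
        "base_truth": TruthParams,
        "optics": Optics,
        "contamination": Contamination,
        "sif_gpp": SifGppConfig,
    }
    kwargs = {}
    for key, cls in nested.items():
        if key in scene_raw:
            kwargs[key] = cls(**_build(cls, dict(scene_raw.pop(key)),
                                       f"scene.{key}"))
    for k in ("years", "lat_range"):
        if k in scene_raw:
            scene_raw[k] = tuple(scene_raw[k])
    if "seed" not in scene_raw:
        raise ValueError("scene.seed must be set explicitly in the config")
    scene = SceneConfig(**_build(SceneConfig, scene_raw, "scene"), **kwargs)

    vi_raw = _build(VIOptions, dict(raw.pop("vi_options", {})), "vi_options")
    fit_raw = _build(FitOptions, dict(raw.pop("fit_options", {})),
                     "fit_options")
    top = {"indices": tuple(raw.pop("indices", DEFAULT_INDICES)),
           "write_scene_nc": bool(raw.pop("write_scene_nc", False))}
    if raw:
        raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
    return PipelineConfig(scene=scene, vi_options=VIOptions(**vi_raw),
                          fit_options=FitOptions(**fit_raw), **top)


def run_pipeline(config: PipelineConfig, outdir: str):
    """Execute synth -> vi -> fit -> pheno (-> trend) and write artifacts.

    Outputs land in ``outdir``: the metric table (``metrics.csv``), the
    truth table (``truth.csv``), per-region trend tables when the scene has
    >= 4 years (``trends.csv``), optionally the scene NetCDF, and the run
    manifest (``manifest.json``, written last). A failing stage leaves
    earlier outputs intact and is recorded in the manifest.
    """
    import os

    from . import __version__

    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(
        config_hash=RunManifest.hash_config(config.to_dict()),
        software_version=__version__,
        seed=config.scene.seed,
    )
    artifacts = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest.failed_stage = name
            manifest.warnings.append(f"{name}: {exc}")
            manifest.write(os.path.join(outdir, "manifest.json"))
            raise
        manifest.stages[name] = round(time.perf_counter() - t0, 3)
        return result

    scene = _stage("synth", lambda: generate_scene(config.scene))
    if config.write_scene_nc:
        path = os.path.join(outdir, "scene.nc")
        _stage("write_scene", lambda: write_scene(scene.reflectance, path))
        manifest.outputs["scene"] = path

    composites = _stage("vi", lambda: compute_vi_composites(
        scene.reflectance, config.indices, config.vi_options))
    metrics = _stage("pheno", lambda: extract_metrics_cube(
        composites, config.fit_options))

    years = list(composites["years"])
    mpath = os.path.join(outdir, "metrics.csv")
    _stage("write_metrics", lambda: write_metrics_csv(metrics, years, mpath))
    manifest.outputs["metrics"] = mpath

    tpath = os.path.join(outdir, "truth.csv")
    def _write_truth():
        df = scene.truth.to_dataframe().reset_index()
        tm = scene.true_metrics.to_dataframe().reset_index()
        df = df.merge(tm, on=["year", "y", "x"])
        tmp = f"{tpath}.tmp"
        df.to_csv(tmp, index=False, float_format="%.6f")
        os.replace(tmp, tpath)
    _stage("write_truth", _write_truth)
    manifest.outputs["truth"] = tpath

    if len(years) >= 4:
        rows = []
        regions = np.zeros((config.scene.ny, config.scene.nx), dtype=int)
        for name, per_metric in metrics.items():
            for metric, cube in per_metric.items():
                tm = trend_map(cube, years=np.asarray(years, dtype=float))
                summary = region_summary(cube, regions,
                                         years=np.asarray(years, float),
                                         trends=tm)
                summary.insert(0, "metric", metric)
                summary.insert(0, "index", name)
                rows.append(summary)
        trpath = os.path.join(outdir, "trends.csv")
        def _write_trends():
            import pandas as pd
            tmp = f"{trpath}.tmp"
            pd.concat(rows, ignore_index=True).to_csv(
                tmp, index=False, float_format="%.6f")
            os.replace(tmp, trpath)
        _stage("trend", _write_trends)
        manifest.outputs["trends"] = trpath

    artifacts["metrics"] = metrics
    artifacts["composites"] = composites
    artifacts["scene"] = scene
    manifest.write(os.path.join(outdir, "manifest.json"))
    artifacts["manifest"] = manifest
    return artifacts
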
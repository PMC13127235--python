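"""Readers, writers, and the run manifest.

Cubes travel as NetCDF (via xarray's scipy backend, NetCDF3 classic),
tables as CSV, summaries and manifests as JSON. The time axis is an
integer day index over 365-day years with ``doy`` and ``cal_year``
auxiliary coordinates; QA is int8 (1 = good, 0 = poor).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "write_scene",
    "read_scene",
    "scene_from_site_csv",
    "read_site_csv",
    "write_metrics_csv",
    "RunManifest",
]

_SCENE_VARS = ("blue", "red", "nir", "qa")


def write_scene(reflectance: xr.Dataset, path: str) -> None:
    """Write a reflectance cube (blue/red/nir/qa over time, y, x) to NetCDF."""
    missing = [v for v in _SCENE_VARS if v not in reflectance]
    if missing:
        raise ValueError(f"scene dataset lacks variables: {missing}")
    tmp = f"{path}.tmp"
    reflectance.to_netcdf(tmp, engine="scipy")
    os.replace(tmp, path)


def read_scene(path: str) -> xr.Dataset:
    """Read and validate a scene cube written by :func:`write_scene`.

    Checks the required variables, a monotone time axis, and coerces QA to
    int8 good/poor. Errors name the offending file and variable.
    """
    ds = xr.open_dataset(path, engine="scipy").load()
    for v in _SCENE_VARS:
        if v not in ds:
            raise ValueError(f"{path}: missing variable '{v}'")
    t = ds["time"].values
    if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
        raise ValueError(f"{path}: time axis must be strictly increasing")
    ds["qa"] = ds["qa"].astype(np.int8)
    for v in ("blue", "red", "nir"):
        vals = ds[v].values
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{path}: variable '{v}' outside [0, 1]")
    return ds


def scene_from_site_csv(path: str) -> xr.Dataset:
    """Build a 1x1 reflectance cube from a site CSV.

    Expected columns: ``doy`` (or ``time``), ``blue``, ``red``, ``nir``,
    ``qa`` (1/0 or good/poor), optionally ``year``.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("blue", "red", "nir", "qa"):
        if req not in cols:
            raise ValueError(f"{path}: missing column '{req}'")
    if "doy" in cols:
        doy = df[cols["doy"]].to_numpy()
    elif "time" in cols:
        doy = df[cols["time"]].to_numpy()
    else:
        raise ValueError(f"{path}: need a 'doy' or 'time' column")
    qa = df[cols["qa"]]
    if qa.dtype == object:
        qa = qa.str.lower().map({"good": 1, "poor": 0})
        if qa.isna().any():
            raise ValueError(f"{path}: unparseable qa values")
    qa = qa.to_numpy().astype(np.int8)
    year = (df[cols["year"]].to_numpy() if "year" in cols
            else np.zeros(len(df), dtype=int))
    t = np.arange(len(df))
    data = {
        v: (("time", "y", "x"),
            df[cols[v]].to_numpy(dtype=float)[:, None, None])
        for v in ("blue", "red", "nir")
    }
    data["qa"] = (("time", "y", "x"), qa[:, None, None])
    return xr.Dataset(
        data,
        coords={"time": t, "doy": ("time", doy.astype(int)),
                "cal_year": ("time", year),
                "y": [0], "x": [0]},
        attrs={"qa_convention": "1 = good, 0 = poor"},
    )


def read_site_csv(path: str) -> pd.DataFrame:
    """Read a tower-style reference CSV (columns: doy [, year], gpp [, sif])."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "doy" not in cols or "gpp" not in cols:
        raise ValueError(f"{path}: need at least 'doy' and 'gpp' columns")
    out = pd.DataFrame({"doy": df[cols["doy"]].to_numpy()})
    out["gpp"] = df[cols["gpp"]].to_numpy(dtype=float)
    if "sif" in cols:
        out["sif"] = df[cols["sif"]].to_numpy(dtype=float)
    if "year" in cols:
        out["year"] = df[cols["year"]].to_numpy()
    return out


def write_metrics_csv(metrics: dict, years, path: str) -> pd.DataFrame:
    """Write a tidy metric table: pixel, year, index, metric, value, valid.

    ``metrics`` maps index name -> {metric name -> (year, y, x) array}.
    Values are written at full precision; consumers round for display.
    """
    rows = []
    for index_name, per_metric in metrics.items():
        for metric_name, cube in per_metric.items():
            cube = np.asarray(cube)
            n_years, ny, nx = cube.shape
            for t in range(n_years):
                for r in range(ny):
                    for c in range(nx):
                        v = cube[t, r, c]
                        rows.append((r, c, years[t], index_name, metric_name,
                                     v, bool(np.isfinite(v))))
    df = pd.DataFrame(rows, columns=["row", "col", "year", "index",
                                     "metric", "value", "valid"])
    tmp = f"{path}.tmp"
    df.to_csv(tmp, index=False, float_format="%.6f")
    os.replace(tmp, path)
    return df


@dataclass
class RunManifest:
    """Provenance record emitted by every pipeline run."""

    config_hash: str
    software_version: str
    seed: int
    stages: dict = field(default_factory=dict)   # stage -> seconds
    outputs: dict = field(default_factory=dict)  # name -> path
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None

    @staticmethod
    def hash_config(config_dict: dict) -> str:
        blob = json.dumps(config_dict, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write(self, path: str) -> None:
        tmp = f"{path}.tmp"
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        os.replace(tmp, path)
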
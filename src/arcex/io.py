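"""Readers and writers for the pipeline's file formats.

Climate cubes travel as NetCDF with CF-like names (``tasmax``, ``pr``,
``prsn``, ``swe``); units are normalised on read to °C, mm/day and mm
SWE.  Events and summaries are CSV, trees newick, fits JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "read_climate",
    "write_climate",
    "write_events",
    "read_events",
    "write_fit",
]

_REQUIRED = ("tasmax", "pr", "swe")


def read_climate(path, rename: dict[str, str] | None = None) -> xr.Dataset:
    """Read a climate cube and normalise its units.

    Temperature in Kelvin (units attr ``K`` or clearly Kelvin-ranged
    values) is converted to °C; snow depth in metres of water equivalent
    (units ``m``) is converted to mm SWE.  Missing required variables
    raise with the variable named.
    """
    path = Path(path)
    try:
        ds = xr.open_dataset(path).load()
    except Exception as exc:  # unparseable / truncated file
        raise ValueError(f"could not read climate cube {path}: {exc}") from exc
    if rename:
        ds = ds.rename(rename)
    for var in _REQUIRED:
        if var not in ds:
            raise ValueError(f"climate cube {path} is missing variable {var!r}")
    tas = ds["tasmax"]
    units = str(tas.attrs.get("units", "")).lower()
    if units in ("k", "kelvin") or float(tas.min()) > 150.0:
        ds["tasmax"] = tas - 273.15
        ds["tasmax"].attrs["units"] = "degC"
    swe = ds["swe"]
    if str(swe.attrs.get("units", "")).lower() in ("m", "metres", "meters"):
        ds["swe"] = swe * 1000.0
        ds["swe"].attrs["units"] = "mm"
    ds.attrs.setdefault("source", str(path))
    return ds


def write_climate(cube: xr.Dataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cube.to_netcdf(path)
    return path


def write_events(events, path) -> Path:
    """Write detected events as tidy CSV (ISO-8601 dates)."""
    from .climate_events import events_to_frame

    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, date_format="%Y-%m-%d")
    return path


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["start_date"])


def write_fit(fit_result, path) -> Path:
    """Serialise a MetaFit as JSON (coefficient table inlined)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "coefficients": fit_result.coefficients.to_dict(orient="records"),
        "sigma2": fit_result.sigma2,
        "loglik": fit_result.loglik,
        "n_records": fit_result.n_records,
        "n_studies": fit_result.n_studies,
        "converged": fit_result.converged,
        "i2_total": fit_result.i2_total,
        "i2_levels": fit_result.i2_levels,
        "q_m": fit_result.q_m,
        "q_m_df": fit_result.q_m_df,
        "q_m_p": fit_result.q_m_p,
        "r2_marginal": fit_result.r2_marginal,
        "diagnostics": fit_result.diagnostics,
    }
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
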
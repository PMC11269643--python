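"""Serialization helpers: CF-style NetCDF for grids, CSV/JSON for tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .envelope import Envelope

__all__ = [
    "write_netcdf",
    "read_netcdf",
    "write_occurrences",
    "read_occurrences",
    "envelopes_to_json",
    "write_json",
]


def write_netcdf(ds: xr.Dataset, path: str | Path) -> Path:
    """Write a dataset as NetCDF3-classic (scipy engine; no netCDF4 needed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_occurrences(df: pd.DataFrame, path: str | Path) -> Path:
    """Occurrence table as CSV plus a JSON ground-truth sidecar if present."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    truth = df.attrs.get("ground_truth")
    if truth is not None:
        write_json(truth, path.with_suffix(".truth.json"))
    return path


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lon", "lat", "species", "present"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing column(s): {sorted(missing)}")
    return df


def envelopes_to_json(envelopes: dict[tuple[str, str], Envelope]) -> dict:
    return {
        f"{sp}|{var}": asdict(env) for (sp, var), env in sorted(envelopes.items())
    }


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, default=str))
    return path
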
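"""Reading and writing daily forcing tables and configuration files.

Forcing travels as CSV (one row per day) or NetCDF (via xarray, one
``day_index`` dimension).  The reader validates the time axis: duplicated
or non-monotone days are errors; interior gaps are errors by default, with
opt-in linear filling of gaps up to three days.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

REQUIRED = ("day_index", "precip", "temp", "et")
OPTIONAL = ("pet", "netrad", "swrad", "sif")

# NetCDF3 through scipy: self-contained, text-tool friendly, no extra deps
NETCDF_KW = dict(engine="scipy")


def read_forcing(
    path: str | Path, fmt: str | None = None, fill_gaps: bool = False
) -> pd.DataFrame:
    """Read a daily forcing table from CSV or NetCDF.

    ``fmt`` is inferred from the suffix when omitted.  ``fill_gaps`` allows
    linear interpolation over interior gaps of at most 3 days; otherwise a
    gap is an error.
    """
    path = Path(path)
    fmt = fmt or ("netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "netcdf":
        ds = xr.open_dataset(path, **NETCDF_KW)
        df = ds.to_dataframe().reset_index()
    else:
        raise ValueError(f"unknown format {fmt!r}")

    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"forcing table missing required column(s): {missing}")

    days = df["day_index"].to_numpy()
    dup = pd.Series(days)[pd.Series(days).duplicated()]
    if len(dup):
        raise ValueError(f"duplicated day_index: day {int(dup.iloc[0])}")
    if np.any(np.diff(days) < 0):
        raise ValueError("day_index must be non-decreasing")

    step = np.diff(days)
    if np.any(step > 1):
        if not fill_gaps:
            first_gap = int(days[np.argmax(step > 1)])
            raise ValueError(
                f"gap in day_index after day {first_gap}; pass fill_gaps=True "
                "to interpolate gaps of up to 3 days"
            )
        if np.any(step > 4):
            raise ValueError("gaps longer than 3 days cannot be filled")
        full = pd.DataFrame({"day_index": np.arange(days[0], days[-1] + 1)})
        df = full.merge(df, on="day_index", how="left").interpolate(
            method="linear", limit_direction="both"
        )
    return df.reset_index(drop=True)


def write_forcing(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a daily forcing table as CSV or NetCDF (round-trip safe)."""
    path = Path(path)
    fmt = fmt or ("netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv")
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "netcdf":
        ds = xr.Dataset.from_dataframe(df.set_index("day_index"))
        ds.to_netcdf(path, **NETCDF_KW)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON-compatible) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
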
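"""CSV readers/writers with schema validation for the four input tables.

Formats (headers are fixed; extra columns are warned about, missing
required columns are fatal):

* fixes:         id,timestamp,lat,lon[,true_state]   (ISO-8601 UTC timestamps)
* isotopes:      id,sex,year,d13C,d15N
* morphometrics: id,sex,year,mass_g,culmen_mm,tarsus_mm,wing_mm
* regurgitates:  sample_id,sex,year,species,length_mm,mass_g
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "read_fixes",
    "write_fixes",
    "read_isotopes",
    "read_morpho",
    "read_regurgitates",
]

_SCHEMAS = {
    "fixes": ["id", "timestamp", "lat", "lon"],
    "isotopes": ["id", "sex", "year", "d13C", "d15N"],
    "morpho": ["id", "sex", "year", "mass_g", "culmen_mm", "tarsus_mm", "wing_mm"],
    "regurgitates": ["sample_id", "sex", "year", "species", "length_mm", "mass_g"],
}
_OPTIONAL = {"fixes": ["true_state"], "isotopes": ["group"]}


def _read(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    required = _SCHEMAS[kind]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required)
    if df.empty and not df.columns.tolist():
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required + _OPTIONAL.get(kind, [])]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
        df = df.drop(columns=extra)
    return df


def read_fixes(path) -> pd.DataFrame:
    """Read a GPS fix table; timestamps must be timezone-aware (UTC)."""
    df = _read(path, "fixes")
    if df.empty:
        return df
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=False, format="ISO8601")
    bad = ts.isna()
    if bad.any():
        raise ValueError(f"{path}: malformed timestamp at row {int(bad.idxmax())}")
    if ts.dt.tz is None:
        raise ValueError(f"{path}: timestamps are timezone-naive; use ISO-8601 with an offset (e.g. ...Z)")
    df["timestamp"] = ts.dt.tz_convert("UTC")
    for col in ("lat", "lon"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"{path}: non-numeric {col} at row {int(vals.isna().idxmax())}")
        df[col] = vals
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValueError(f"{path}: coordinates out of range")
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def _numeric(df, cols, path):
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"{path}: non-numeric {col} at row {int(vals.isna().idxmax())}")
        df[col] = vals
    return df


def read_isotopes(path) -> pd.DataFrame:
    df = _read(path, "isotopes")
    return df if df.empty else _numeric(df, ["d13C", "d15N"], path)


def read_morpho(path) -> pd.DataFrame:
    df = _read(path, "morpho")
    return df if df.empty else _numeric(df, ["mass_g", "culmen_mm", "tarsus_mm", "wing_mm"], path)


def read_regurgitates(path) -> pd.DataFrame:
    df = _read(path, "regurgitates")
    return df if df.empty else _numeric(df, ["length_mm", "mass_g"], path)
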
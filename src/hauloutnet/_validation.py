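"""Shared input-validation helpers."""

from __future__ import annotations

import pandas as pd


class OrderingError(ValueError):
    """Records are not sorted in time within a seal."""


class ParseError(ValueError):
    """Input does not conform to the expected schema."""


def as_timedelta(value, name: str) -> pd.Timedelta:
    """Coerce ``value`` (str like '10min', numeric seconds, or Timedelta) to Timedelta."""
    if isinstance(value, pd.Timedelta):
        td = value
    elif isinstance(value, (int, float)):
        td = pd.Timedelta(seconds=float(value))
    else:
        td = pd.Timedelta(value)
    if td <= pd.Timedelta(0):
        raise ValueError(f"{name} must be positive, got {value!r}")
    return td


def as_utc(series: pd.Series) -> pd.Series:
    """Parse a column to timezone-aware UTC timestamps."""
    out = pd.to_datetime(series, utc=True, format="ISO8601" if series.dtype == object else None)
    if out.isna().any():
        raise ParseError("unparseable timestamps present")
    return out


def require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{what} is missing required columns {missing}; has {list(df.columns)}")


def check_coordinates(lon, lat) -> None:
    import numpy as np

    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValueError("coordinates out of range: |lon| <= 180 and |lat| <= 90 required")
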
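"""Reading, validating and writing the daily-series table.

The pipeline's sole input is a CSV with one row per calendar day carrying
cause-specific death counts, PM2.5, temperature, wind speed, boundary-layer
height and ozone.  Validation is strict and names offending rows: analyses
downstream assume consecutive dates and nonnegative counts, and silently
broken inputs would corrupt every spline of time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["REQUIRED_COLUMNS", "read_daily_series", "validate_daily_series", "write_daily_series"]

REQUIRED_COLUMNS = (
    "date",
    "deaths_cvd", "deaths_ihd", "deaths_mi", "deaths_cva", "deaths_htn",
    "pm25", "tem", "ws", "blh", "ozone",
)

_COUNT_COLUMNS = tuple(c for c in REQUIRED_COLUMNS if c.startswith("deaths_"))


def validate_daily_series(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily-series table and return a normalised copy.

    Checks: all required columns present; dates parse, strictly increase and
    have no gaps; counts are nonnegative integers; pm25 > 0; blh > 0; ws >= 0;
    no missing values.  Adds a ``dow`` column (0 = Monday) derived from the
    date.  Row numbers in error messages are 1-based data rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"], errors="raise")
    if len(df) == 0:
        raise ValidationError("daily series is empty")

    na_rows = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if na_rows.any():
        rows = (np.flatnonzero(na_rows) + 1)[:10].tolist()
        raise ValidationError(f"missing values at rows {rows}")

    deltas = df["date"].diff().dt.days.iloc[1:]
    if (deltas <= 0).any():
        rows = (np.flatnonzero(deltas.to_numpy() <= 0) + 2)[:10].tolist()
        raise ValidationError(f"dates not strictly increasing at rows {rows}")
    if (deltas > 1).any():
        i = int(np.flatnonzero(deltas.to_numpy() > 1)[0]) + 1
        gap = (df['date'].iloc[i - 1].date(), df['date'].iloc[i].date())
        raise ValidationError(f"date gap between {gap[0]} and {gap[1]} (rows {i}, {i + 1})")

    for col in _COUNT_COLUMNS:
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            rows = (np.flatnonzero(~np.isclose(vals, np.round(vals))) + 1)[:10].tolist()
            raise ValidationError(f"{col} has non-integer values at rows {rows}")
        if (vals < 0).any():
            rows = (np.flatnonzero(vals < 0) + 1)[:10].tolist()
            raise ValidationError(f"{col} has negative counts at rows {rows}")
        df[col] = vals.astype(int)

    for col, lo, strict in (("pm25", 0.0, True), ("blh", 0.0, True), ("ws", 0.0, False)):
        vals = df[col].to_numpy(dtype=float)
        bad = vals <= lo if strict else vals < lo
        if bad.any():
            rows = (np.flatnonzero(bad) + 1)[:10].tolist()
            op = "<=" if strict else "<"
            raise ValidationError(f"{col} {op} {lo} at rows {rows}")

    df["dow"] = df["date"].dt.dayofweek
    return df.reset_index(drop=True)


def read_daily_series(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a daily-series CSV.

    ``column_map`` maps canonical names (see :data:`REQUIRED_COLUMNS`) to the
    column names used in the file, so externally formatted tables can be
    ingested without code changes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"daily series file not found: {path}")
    df = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        absent = [src for src in rename if src not in df.columns]
        if absent:
            raise ValidationError(f"column map refers to absent columns: {absent}")
        df = df.rename(columns=rename)
    return validate_daily_series(df)


def write_daily_series(df: pd.DataFrame, path: str | Path) -> None:
    """Write a daily series as CSV with ISO-8601 dates (the package dialect)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.drop(columns=[c for c in ("dow",) if c in out.columns], inplace=True)
    out.to_csv(path, index=False)
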
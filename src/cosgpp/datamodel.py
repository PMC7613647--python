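"""Half-hourly flux/meteorology data model, validation, and u* filtering.

The exchange unit for every stage of the pipeline is a pandas DataFrame on a
strict 30-minute DatetimeIndex (local standard time, no DST) with the
canonical columns below.  Fluxes carry a provenance flag column
(``nee_flag``, ``fcos_flag``) taking the values ``measured``, ``gapfilled``
or ``missing``; meteorological variables signal missingness with NaN.

Sign conventions: NEE positive upward (emission to the atmosphere), GPP
reported positive, COS flux negative for uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURED = "measured"
GAPFILLED = "gapfilled"
MISSING = "missing"

#: canonical numeric columns, in CSV order
NUMERIC_COLUMNS = [
    "nee",       # umol CO2 m-2 s-1, positive = emission
    "fcos",      # pmol COS m-2 s-1, negative = uptake
    "ustar",     # m s-1
    "t_air",     # degC at reference height
    "t_soil",    # degC at 2-5 cm
    "par",       # umol photons m-2 s-1
    "vpd",       # kPa
    "swc",       # m3 m-3
    "co2_ppm",   # umol mol-1
    "cos_ppt",   # pmol mol-1
]

FLAG_COLUMNS = ["nee_flag", "fcos_flag"]

#: default friction-velocity threshold (m s-1) below which eddy fluxes are
#: rejected as unreliable low-turbulence periods
USTAR_THRESHOLD = 0.3

GRID_FREQ = "30min"


class ValidationError(ValueError):
    """Raised on structural defects that cannot be repaired (bad grid)."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_series`."""

    frame: pd.DataFrame
    n_inserted: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)


def _ensure_datetime_index(df: pd.DataFrame) -> pd.DataFrame:
    if "timestamp" in df.columns:
        df = df.set_index("timestamp")
    idx = pd.DatetimeIndex(pd.to_datetime(df.index))
    df = df.copy()
    df.index = idx
    df.index.name = "timestamp"
    return df


def validate_series(df: pd.DataFrame) -> ValidationReport:
    """Regularize a half-hourly series and enforce physical bounds.

    * timestamps must be strictly increasing with no duplicates (hard error);
    * missing half-hours are inserted as rows flagged ``missing``;
    * physically impossible values (par < 0, vpd < 0, swc outside [0, 1],
      non-positive mixing ratios) are set to NaN with a warning;
    * flux flags are initialised to ``measured`` where finite and ``missing``
      where NaN, unless a flag column is already present.
    """
    df = _ensure_datetime_index(df)
    if df.index.has_duplicates:
        raise ValidationError("duplicate timestamps in input")
    if not df.index.is_monotonic_increasing:
        raise ValidationError("timestamps are not strictly increasing")
    if len(df) == 0:
        raise ValidationError("empty series")

    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # snap to the full 30-min grid
    full = pd.date_range(df.index[0], df.index[-1], freq=GRID_FREQ)
    if not df.index.isin(full).all():
        raise ValidationError("timestamps are not aligned on a 30-min grid")
    n_inserted = len(full) - len(df)
    df = df.reindex(full)
    df.index.name = "timestamp"

    msgs: list[str] = []

    def _reject(col: str, bad: pd.Series, reason: str) -> None:
        n = int(bad.sum())
        if n:
            df.loc[bad, col] = np.nan
            msgs.append(f"{col}: {n} value(s) {reason}, flagged missing")

    _reject("par", df["par"] < 0, "below 0")
    _reject("vpd", df["vpd"] < 0, "below 0")
    _reject("swc", (df["swc"] < 0) | (df["swc"] > 1), "outside [0, 1]")
    _reject("co2_ppm", df["co2_ppm"] <= 0, "non-positive")
    _reject("cos_ppt", df["cos_ppt"] <= 0, "non-positive")
    _reject("ustar", df["ustar"] < 0, "below 0")

    for flux, flag in zip(("nee", "fcos"), FLAG_COLUMNS):
        if flag not in df.columns:
            df[flag] = np.where(np.isfinite(df[flux]), MEASURED, MISSING)
        else:
            df[flag] = df[flag].fillna(MISSING)
            df.loc[~np.isfinite(df[flux]), flag] = MISSING
        df[flag] = df[flag].astype(str)
        # flagged-missing values must never reach a fit or mean
        df.loc[df[flag] == MISSING, flux] = np.nan

    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return ValidationReport(frame=df, n_inserted=n_inserted, warnings=msgs)


def apply_ustar_filter(
    df: pd.DataFrame, threshold: float = USTAR_THRESHOLD
) -> pd.DataFrame:
    """Flag NEE and FCOS as missing where u* < threshold.

    Rows with u* exactly at the threshold are retained (the rule is a strict
    "<").  Rows with unknown u* are rejected as unverifiable.  Meteorology is
    untouched, and the operation is idempotent: numeric flux values are only
    erased, never altered.
    """
    if not np.isfinite(df["ustar"]).any():
        raise ValidationError("u* is missing for the entire series")
    out = df.copy()
    low = ~(out["ustar"] >= threshold)  # catches NaN as well
    for flux, flag in zip(("nee", "fcos"), FLAG_COLUMNS):
        out.loc[low, flux] = np.nan
        out.loc[low, flag] = MISSING
    return out


def blended_temperature(t_air, t_soil):
    """Arithmetic mean of air and shallow-soil temperature (degC).

    This blended temperature is the ecosystem-respiration driver; either
    input missing yields a missing result.
    """
    return (np.asarray(t_air, dtype=float) + np.asarray(t_soil, dtype=float)) / 2.0


def read_series_csv(path, column_map: dict[str, str] | None = None) -> ValidationReport:
    """Read a canonical CSV (optionally renaming user columns) and validate."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return validate_series(df)


def write_series_csv(df: pd.DataFrame, path) -> None:
    """Write a validated series; round-trips values and flags exactly."""
    cols = [c for c in NUMERIC_COLUMNS + FLAG_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=True, index_label="timestamp")
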
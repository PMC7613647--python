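"""Method-labelled GPP time series with per-value provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GAPFILLED, MEASURED, MISSING


@dataclass
class GPPSeries:
    """GPP (umol m-2 s-1) on the half-hourly master grid.

    ``flag`` records whether each value derives from a measured flux, a
    gap-filling model, or is absent; every aggregation rule downstream keys
    on this provenance.  ``resp`` optionally carries the modelled ecosystem
    respiration of a partitioning method.
    """

    method: str
    gpp: pd.Series
    flag: pd.Series
    resp: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gpp.index.equals(self.flag.index):
            raise ValueError("gpp and flag must share one index")
        bad = ~self.flag.isin([MEASURED, GAPFILLED, MISSING])
        if bad.any():
            raise ValueError(f"unknown flag value(s): {set(self.flag[bad])}")

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.gpp.index

    @property
    def available(self) -> pd.Series:
        """Boolean mask of usable (measured or gap-filled) values."""
        return self.flag.ne(MISSING) & np.isfinite(self.gpp)

    @property
    def measured(self) -> pd.Series:
        """Boolean mask of measured-provenance values only."""
        return self.flag.eq(MEASURED) & np.isfinite(self.gpp)

    @property
    def gapfilled_fraction(self) -> float:
        avail = self.available
        if not avail.any():
            return float("nan")
        return float(self.flag.eq(GAPFILLED)[avail].mean())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gpp": self.gpp, "flag": self.flag})
        if self.resp is not None:
            out["resp"] = self.resp
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, method: str) -> "GPPSeries":
        idx = pd.DatetimeIndex(pd.to_datetime(frame.index))
        gpp = pd.Series(frame["gpp"].to_numpy(dtype=float), index=idx)
        flag = pd.Series(frame["flag"].astype(str).to_numpy(), index=idx, dtype=object)
        resp = None
        if "resp" in frame.columns:
            resp = pd.Series(frame["resp"].to_numpy(dtype=float), index=idx)
        return cls(method=method, gpp=gpp, flag=flag, resp=resp)
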
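"""Temporal aggregation, availability rules and cross-method comparison.

The averaging protocol keys on provenance:

* a daily mean exists only when strictly more than 50% of the day's 48
  half hours carry a *measured* flux (the mean itself then uses all
  available values, measured and gap-filled, so that daily estimates
  reflect measurements rather than the gap-filling model);
* monthly means are unweighted means of the daily means;
* diurnal composites are medians per half-hour-of-day over a month,
  computed on the common mask of all compared methods, and a month enters
  only above 55% common coverage (strict);
* cumulative sums integrate the gap-filled series (48 x 1800 s half hours,
  12.011e-6 gC per umol CO2) and report the gap-filled fraction;
* method comparisons use measured data only, on the common mask, with
  median relative differences against a reference and a one-way ANOVA
  across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MEASURED
from .gppseries import GPPSeries

SECONDS_PER_HALFHOUR = 1800.0
GC_PER_UMOL = 12.011e-6
SLOTS_PER_DAY = 48

DAILY_MEASURED_FRACTION = 0.5
DIURNAL_COVERAGE_FRACTION = 0.55


def daily_mean(series: GPPSeries,
               measured_fraction: float = DAILY_MEASURED_FRACTION) -> pd.Series:
    """Daily mean GPP; a day exists iff measured coverage > the threshold.

    The comparison is strict, so 24/48 measured half hours is excluded and
    25/48 included at the default threshold.
    """
    by_day = series.gpp.groupby(series.index.normalize())
    measured_count = series.measured.groupby(series.index.normalize()).sum()
    means = series.gpp[series.available].groupby(
        series.index[series.available].normalize()
    ).mean()
    ok_days = measured_count[measured_count / SLOTS_PER_DAY > measured_fraction].index
    out = means.reindex(ok_days.intersection(means.index))
    out.index.name = "date"
    return out


def monthly_mean(daily: pd.Series, min_days: int = 1) -> pd.Series:
    """Unweighted mean of available daily means per calendar month."""
    grouped = daily.groupby(daily.index.to_period("M"))
    counts = grouped.count()
    means = grouped.mean()
    return means[counts >= min_days]


def common_mask(series_list: list[GPPSeries], measured_only: bool = True) -> pd.Series:
    """Boolean mask of timestamps usable in every series.

    Shrinking any input's coverage can only shrink the mask (intersection
    is monotone).
    """
    if not series_list:
        raise ValueError("need at least one series")
    idx = series_list[0].index
    mask = pd.Series(True, index=idx)
    for s in series_list:
        if not s.index.equals(idx):
            raise ValueError("series are not on one master grid")
        mask &= s.measured if measured_only else s.available
    return mask


def diurnal_median(
    series_list: list[GPPSeries],
    coverage_threshold: float = DIURNAL_COVERAGE_FRACTION,
) -> dict[pd.Period, pd.DataFrame]:
    """Per-month median diurnal cycles on the common (gap-filled) mask.

    Returns a mapping month -> 48-row frame (index = half-hour of day,
    one column per method).  Months at or below the coverage threshold on
    the common mask are excluded.
    """
    mask = common_mask(series_list, measured_only=False)
    idx = series_list[0].index
    months = pd.PeriodIndex(idx, freq="M")
    out: dict[pd.Period, pd.DataFrame] = {}
    for month in months.unique():
        in_month = months == month
        n_slots = int(in_month.sum())
        covered = mask[in_month]
        if n_slots == 0 or covered.sum() / n_slots <= coverage_threshold:
            continue
        sel = in_month & mask.to_numpy()
        slot = idx[sel].hour * 2 + idx[sel].minute // 30
        cols = {}
        for s in series_list:
            cols[s.method] = s.gpp[sel].groupby(slot).median()
        frame = pd.DataFrame(cols).reindex(range(SLOTS_PER_DAY))
        frame.index.name = "halfhour_of_day"
        out[month] = frame
    return out


@dataclass
class CumulativeResult:
    """Period-integrated GPP and the provenance of the values summed."""

    total_gc_m2: float
    gapfilled_fraction: float
    n_halfhours: int


def cumulative_gpp(
    series: GPPSeries,
    start="2017-05-01",
    end="2017-07-31",
) -> CumulativeResult:
    """Cumulative GPP (gC m-2) over [start, end] inclusive of the end day.

    Requires a complete gap-filled series over the period: any missing half
    hour is an error, since a partial sum is not a cumulative total.
    """
    t0 = pd.Timestamp(start)
    t1 = pd.Timestamp(end) + pd.Timedelta(days=1)
    sel = (series.index >= t0) & (series.index < t1)
    if not sel.any():
        raise ValueError("period not covered by the series")
    gpp = series.gpp[sel]
    avail = series.available[sel]
    if not avail.all():
        n_bad = int((~avail).sum())
        raise ValueError(
            f"{n_bad} half hour(s) missing in the period; cumulative sums "
            "require a complete gap-filled series"
        )
    total = float(gpp.sum() * SECONDS_PER_HALFHOUR * GC_PER_UMOL)
    frac = float(series.flag[sel].eq("gapfilled").mean())
    return CumulativeResult(total_gc_m2=total, gapfilled_fraction=frac,
                            n_halfhours=int(sel.sum()))


def binned_response(
    series_list: list[GPPSeries],
    driver: pd.Series,
    n_bins: int = 12,
    par: pd.Series | None = None,
    par_floor: float | None = 700.0,
) -> pd.DataFrame:
    """Equal-count binned response of GPP to an environmental driver.

    Measured values only, on the common mask across methods.  When a PAR
    series is supplied (for non-PAR drivers) rows at or below ``par_floor``
    are dropped first, avoiding the confounding correlation with radiation.
    Bins are equal-count by driver order; with a remainder, sizes differ by
    at most one (larger bins first).
    """
    mask = common_mask(series_list, measured_only=True)
    mask &= np.isfinite(driver)
    if par is not None and par_floor is not None:
        mask &= par > par_floor
    d = driver[mask]
    if len(d) < n_bins:
        raise ValueError(f"only {len(d)} points for {n_bins} bins")
    order = np.argsort(d.to_numpy(), kind="stable")
    chunks = np.array_split(order, n_bins)
    rows = []
    for i, chunk in enumerate(chunks):
        sel = d.index[chunk]
        row = {"bin": i, "n": len(chunk), "driver_mean": float(d.loc[sel].mean())}
        for s in series_list:
            row[s.method] = float(s.gpp.loc[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


@dataclass
class PairDifference:
    """Paired differences of one method against the reference."""

    method: str
    reference: str
    median_relative_pct: float
    q25_relative_pct: float
    q75_relative_pct: float
    median_absolute: float
    n: int


@dataclass
class ComparisonReport:
    """Common-mask differences and ANOVA across GPP methods."""

    timescale: str
    pairs: list[PairDifference]
    anova_f: float
    anova_p: float
    n: int
    methods: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "timescale": self.timescale,
            "n": self.n,
            "anova": {"F": self.anova_f, "p": self.anova_p},
            "pairs": [
                {
                    "method": p.method,
                    "reference": p.reference,
                    "median_relative_pct": p.median_relative_pct,
                    "q25_relative_pct": p.q25_relative_pct,
                    "q75_relative_pct": p.q75_relative_pct,
                    "median_absolute": p.median_absolute,
                    "n": p.n,
                }
                for p in self.pairs
            ],
        }


def _aggregate_masked(values: pd.Series, timescale: str) -> pd.Series:
    if timescale == "30min":
        return values
    daily = values.groupby(values.index.normalize()).mean()
    if timescale == "daily":
        return daily
    if timescale == "monthly":
        return daily.groupby(daily.index.to_period("M")).mean()
    raise ValueError(f"unknown timescale {timescale!r}")


def compare_methods(
    series_list: list[GPPSeries],
    reference: str,
    timescale: str = "daily",
    eps: float = 1e-9,
) -> ComparisonReport:
    """Compare methods on their common measured mask at one timescale.

    Relative difference is (method - reference)/reference per matched cell,
    summarised by the median with quartiles; cells where the reference is
    within ``eps`` of zero are dropped from the relative statistics.  The
    one-way ANOVA treats the aggregated cells of each method as one group.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two series to compare")
    names = [s.method for s in series_list]
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among methods {names}")
    mask = common_mask(series_list, measured_only=True)
    aggregated = {
        s.method: _aggregate_masked(s.gpp[mask], timescale) for s in series_list
    }
    ref = aggregated[reference]
    n = len(ref)
    pairs = []
    for s in series_list:
        if s.method == reference:
            continue
        other = aggregated[s.method]
        diff = other - ref
        ok = np.abs(ref) > eps
        rel = 100.0 * diff[ok] / ref[ok]
        pairs.append(
            PairDifference(
                method=s.method,
                reference=reference,
                median_relative_pct=float(rel.median()) if len(rel) else float("nan"),
                q25_relative_pct=float(rel.quantile(0.25)) if len(rel) else float("nan"),
                q75_relative_pct=float(rel.quantile(0.75)) if len(rel) else float("nan"),
                median_absolute=float(diff.median()) if len(diff) else float("nan"),
                n=len(diff),
            )
        )
    groups = [v.to_numpy() for v in aggregated.values()]
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        f_stat, p_val = 0.0, 1.0  # identical groups: no between-method variance
    else:
        f_stat, p_val = stats.f_oneway(*groups)
    return ComparisonReport(
        timescale=timescale,
        pairs=pairs,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        n=n,
        methods=names,
    )
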
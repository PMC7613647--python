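"""End-to-end orchestration of the GPP estimation workflow.

validate -> u* filter -> COS gap-fill -> NLR partition -> COS proxy GPP
(both LRU models) -> comparison.  Each method is isolated: a failure in
one (for example a missing FCOS column) skips its products and logs the
reason while the others complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregate, cos_gpp, nlr_partition
from .config import SiteConfig
from .datamodel import apply_ustar_filter, validate_series
from .gppseries import GPPSeries

log = logging.getLogger("cosgpp")


@dataclass
class PipelineResult:
    frame: pd.DataFrame
    series: dict[str, GPPSeries] = field(default_factory=dict)
    reports: dict[str, aggregate.ComparisonReport] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    q10: float | None = None
    theta: float | None = None


def run_pipeline(
    df: pd.DataFrame,
    config: SiteConfig | None = None,
    estimate_theta: bool = False,
    external: dict[str, GPPSeries] | None = None,
) -> PipelineResult:
    """Run every GPP method the input supports and compare them.

    ``estimate_theta`` switches on the (slow) curvature search; otherwise
    the default curvature is used.  ``external`` GPP series (for example a
    machine-learning product computed elsewhere) join the comparison.
    """
    config = config or SiteConfig()
    report = validate_series(df)
    for msg in report.warnings:
        log.warning("validate: %s", msg)
    frame = apply_ustar_filter(report.frame, config.ustar_threshold)
    result = PipelineResult(frame=frame)

    # Q10 / theta / windowed NLR partition
    try:
        q10_res = nlr_partition.estimate_q10(frame)
        result.q10 = q10_res.q10
        theta = nlr_partition.THETA_DEFAULT
        if estimate_theta:
            theta = nlr_partition.estimate_theta(frame, q10_res.q10,
                                                 window_days=config.window_days)
        result.theta = theta
        fits = nlr_partition.fit_all_windows(frame, q10_res.q10, theta,
                                             window_days=config.window_days)
        log.info("NLR: fitted %d windows, q10=%.3f theta=%.2f",
                 len(fits), q10_res.q10, theta)
        result.series["NLR"] = nlr_partition.partition(frame, fits)
    except (ValueError, nlr_partition.UnfittableWindowError) as exc:
        result.skipped["NLR"] = str(exc)
        log.warning("NLR skipped: %s", exc)

    # COS-proxy methods
    if np.isfinite(frame["fcos"]).any():
        filled = cos_gpp.gapfill_cos(frame, window_days=config.window_days)
        for model, label in (("par", "COS_PAR"), ("cap", "COS_CAP")):
            try:
                cfg = cos_gpp.COSBudgetConfig(
                    soil_flux=config.soil_cos_flux,
                    lru_model=model,
                    lru_const=config.lru_const,
                    cap_params=config.cap_params,
                    pressure_kpa=config.pressure_kpa,
                )
                result.series[label] = cos_gpp.gpp_cos_series(filled, cfg)
            except (ValueError, RuntimeError) as exc:
                result.skipped[label] = str(exc)
                log.warning("%s skipped: %s", label, exc)
    else:
        result.skipped["COS_PAR"] = result.skipped["COS_CAP"] = "no FCOS data"
        log.warning("COS methods skipped: no FCOS data")

    for label, series in (external or {}).items():
        ingest_external_gpp(series, result)

    if len(result.series) >= 2 and "NLR" in result.series:
        for timescale in ("30min", "daily", "monthly"):
            try:
                result.reports[timescale] = aggregate.compare_methods(
                    list(result.series.values()), reference="NLR",
                    timescale=timescale,
                )
            except ValueError as exc:
                log.warning("comparison at %s skipped: %s", timescale, exc)
    return result


def ingest_external_gpp(series: GPPSeries, result: PipelineResult) -> None:
    """Accept an externally computed GPP series for comparison.

    The grid must match the master half-hourly grid exactly; negative
    external values are only warned about (some external products clamp GPP
    to positive values, so a negative one usually signals a sign slip).
    """
    master = result.frame.index
    if not series.index.equals(master):
        for ts in series.index:
            if ts not in master:
                raise ValueError(f"external series off the master grid at {ts}")
        raise ValueError("external series does not cover the master grid")
    neg = (series.gpp < 0) & series.available
    if neg.any():
        log.warning("external series %s has %d negative GPP value(s)",
                    series.method, int(neg.sum()))
    result.series[series.method] = series
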
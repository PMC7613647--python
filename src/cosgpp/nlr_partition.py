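"""Nighttime/daytime NEE partitioning into respiration and GPP.

The model is NEE = R - GPP with

* ``R = R_c * Q10^(T_sa / 10)`` — ecosystem respiration as a Q10 exponential
  of the blended air/soil temperature ``T_sa`` with ``R_c`` the respiration
  at 0 degC;
* GPP a non-rectangular hyperbola (NRH) of PAR — initial slope ``alpha``,
  asymptote ``P_max`` and curvature ``theta`` — multiplied by a sigmoidal
  temperature gate ``f(T_a)`` that sends GPP to zero at freezing
  temperatures (inflection T0 = -2 degC).

``alpha``, ``P_max`` and ``R_c`` are fitted per 15-day window against
measured NEE with ``Q10`` and ``theta`` held fixed; ``Q10`` comes from a
CI-weighted mean of monthly nighttime fits over the summer months and
``theta`` from a one-dimensional search scored on summer NEE RMSE.
Partitioned GPP on measured rows is ``R - NEE`` (negative excursions from
measurement noise are preserved); gaps are filled from the NRH model
refitted against the partitioned GPP itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .datamodel import GAPFILLED, MEASURED, MISSING, blended_temperature
from .gppseries import GPPSeries

T0_DEFAULT = -2.0
THETA_DEFAULT = 0.9
#: PAR (umol m-2 s-1) below which a half hour counts as night
NIGHT_PAR_MAX = 10.0
#: optimiser box for (alpha, p_max, r_c) and the deterministic start point
_FIT_BOUNDS = ([1e-8, 1e-6, 1e-6], [0.2, 60.0, 20.0])
_FIT_X0 = (0.03, 15.0, 2.0)


@dataclass
class PartitionParams:
    """Windowed light-response and respiration parameters.

    alpha : umol CO2 per umol photons, initial slope of the light response
    p_max : umol m-2 s-1, light-saturated GPP
    r_c   : umol m-2 s-1, respiration at 0 degC
    q10   : multiplicative respiration increase per 10 degC
    theta : NRH curvature in (0, 1]
    t0    : degC, inflection of the temperature gate
    window: (start, end] labels of the interval the triplet applies to
    """

    alpha: float
    p_max: float
    r_c: float
    q10: float
    theta: float = THETA_DEFAULT
    t0: float = T0_DEFAULT
    window: tuple | None = None
    rmse: float | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        for name in ("alpha", "p_max", "r_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1.0 <= self.q10 <= 5.0:
            warnings.warn(
                f"q10 = {self.q10:.3g} outside the plausible range [1, 5]",
                stacklevel=2,
            )


@dataclass
class Q10Estimate:
    """One monthly Q10 fit and its weight (inverse 95% CI half width)."""

    q10: float
    ci_halfwidth: float
    year: int
    month: int
    n_points: int

    def __post_init__(self) -> None:
        if not self.ci_halfwidth > 0:
            raise ValueError("ci_halfwidth must be positive")

    @property
    def weight(self) -> float:
        return 1.0 / self.ci_halfwidth


@dataclass
class Q10Result:
    """CI-weighted combination of monthly Q10 estimates."""

    q10: float
    monthly: list[Q10Estimate]

    @property
    def ci_halfwidth(self) -> float:
        # variance of the weighted mean under independent monthly estimates,
        # with per-month sd = CI_i / 1.96 and weights w_i = 1 / CI_i
        w = np.array([m.weight for m in self.monthly])
        ci = np.array([m.ci_halfwidth for m in self.monthly])
        return float(np.sqrt(np.sum((w * ci) ** 2)) / np.sum(w))


def respiration(t_sa, r_c: float, q10: float):
    """Q10 respiration (umol m-2 s-1) at blended temperature t_sa (degC)."""
    return r_c * np.power(q10, np.asarray(t_sa, dtype=float) / 10.0)


def temperature_gate(t_air, t0: float = T0_DEFAULT):
    """Sigmoid in (0, 1) gating GPP towards zero at freezing temperatures."""
    return 1.0 / (1.0 + np.exp(2.0 * (t0 - np.asarray(t_air, dtype=float))))


def gpp_light_response(par, t_air, params: PartitionParams):
    """Non-rectangular hyperbola GPP (umol m-2 s-1).

    GPP = [aI + Pmax - sqrt((aI + Pmax)^2 - 4 theta aI Pmax)] f(Ta) / (2 theta)

    with ``aI = alpha * PAR``.  As theta -> 0 this degenerates continuously
    to the rectangular hyperbola ``aI * Pmax / (aI + Pmax) * f(Ta)``, which
    is used directly below theta = 1e-9 for numerical stability.
    """
    par = np.asarray(par, dtype=float)
    ai = params.alpha * par
    f = temperature_gate(t_air, params.t0)
    if params.theta < 1e-9:
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(ai + params.p_max > 0, ai * params.p_max / (ai + params.p_max), 0.0)
        return g * f
    s = ai + params.p_max
    disc = s * s - 4.0 * params.theta * ai * params.p_max
    g = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * params.theta)
    return g * f


def model_nee(par, t_air, t_sa, params: PartitionParams):
    """Forward NEE = R(T_sa) - GPP(PAR, T_a)."""
    return respiration(t_sa, params.r_c, params.q10) - gpp_light_response(
        par, t_air, params
    )


class UnfittableWindowError(RuntimeError):
    """The window lacks the data needed to identify (alpha, p_max, r_c)."""


def fit_window_params(
    frame: pd.DataFrame,
    q10: float,
    theta: float = THETA_DEFAULT,
    t0: float = T0_DEFAULT,
    min_points: int = 48,
    window: tuple | None = None,
) -> PartitionParams:
    """Fit (alpha, p_max, r_c) to measured NEE over one window.

    Bounded nonlinear least squares from a fixed start point, so the fit is
    deterministic.  Requires at least ``min_points`` measured half hours and
    some nighttime coverage (r_c is identified only by dark data).
    """
    ok = (frame["nee_flag"] == MEASURED) & np.isfinite(frame["nee"])
    ok &= np.isfinite(frame["par"]) & np.isfinite(frame["t_air"]) & np.isfinite(frame["t_soil"])
    sub = frame.loc[ok]
    if len(sub) < min_points:
        raise UnfittableWindowError(
            f"only {len(sub)} usable points (< {min_points})"
        )
    night = sub["par"] < NIGHT_PAR_MAX
    if not night.any():
        raise UnfittableWindowError("no nighttime points in window")
    if night.all():
        raise UnfittableWindowError("no daytime points in window")

    par = sub["par"].to_numpy()
    t_air = sub["t_air"].to_numpy()
    t_sa = blended_temperature(sub["t_air"], sub["t_soil"])
    nee = sub["nee"].to_numpy()

    def resid(x):
        p = PartitionParams(alpha=x[0], p_max=x[1], r_c=x[2], q10=q10, theta=theta, t0=t0)
        return model_nee(par, t_air, t_sa, p) - nee

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.least_squares(resid, x0=_FIT_X0, bounds=_FIT_BOUNDS)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return PartitionParams(
        alpha=float(sol.x[0]),
        p_max=float(sol.x[1]),
        r_c=float(sol.x[2]),
        q10=q10,
        theta=theta,
        t0=t0,
        window=window,
        rmse=rmse,
        n_points=len(sub),
    )


def iter_windows(index: pd.DatetimeIndex, window_days: int = 15):
    """Consecutive non-overlapping windows anchored at Jan 1 of each year."""
    start = index[0].normalize()
    anchor = pd.Timestamp(year=start.year, month=1, day=1)
    step = pd.Timedelta(days=window_days)
    t = anchor + ((start - anchor) // step) * step
    end = index[-1]
    while t <= end:
        yield (t, t + step)
        t = t + step


def fit_all_windows(
    frame: pd.DataFrame,
    q10: float,
    theta: float = THETA_DEFAULT,
    window_days: int = 15,
    min_points: int = 48,
) -> list[PartitionParams]:
    """Fit every window; unfittable windows inherit interpolated neighbours.

    Interpolation is linear in (alpha, p_max, r_c) between the nearest
    fittable windows on either side; at the edges the nearest fit is carried
    over unchanged.
    """
    fits: list[PartitionParams | None] = []
    wins = list(iter_windows(frame.index, window_days))
    for w0, w1 in wins:
        sub = frame.loc[(frame.index >= w0) & (frame.index < w1)]
        try:
            fits.append(
                fit_window_params(sub, q10, theta, min_points=min_points, window=(w0, w1))
            )
        except UnfittableWindowError:
            fits.append(None)

    good = [i for i, f in enumerate(fits) if f is not None]
    if not good:
        raise UnfittableWindowError("no fittable window in the series")
    for i, f in enumerate(fits):
        if f is not None:
            continue
        left = max((j for j in good if j < i), default=None)
        right = min((j for j in good if j > i), default=None)
        if left is None:
            src = fits[right]
            vals = (src.alpha, src.p_max, src.r_c)
        elif right is None:
            src = fits[left]
            vals = (src.alpha, src.p_max, src.r_c)
        else:
            t = (i - left) / (right - left)
            a, b = fits[left], fits[right]
            vals = tuple(
                (1 - t) * getattr(a, k) + t * getattr(b, k)
                for k in ("alpha", "p_max", "r_c")
            )
        fits[i] = PartitionParams(
            alpha=vals[0], p_max=vals[1], r_c=vals[2],
            q10=q10, theta=theta, window=wins[i], rmse=None, n_points=0,
        )
    return fits  # type: ignore[return-value]


def _fit_night_q10(t_sa: np.ndarray, nee: np.ndarray) -> tuple[float, float]:
    """Fit NEE = r_c * q10^(T_sa/10) to nighttime data; return (q10, 95% CI)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = optimize.curve_fit(
            lambda t, r_c, q10: r_c * np.power(q10, t / 10.0),
            t_sa,
            nee,
            p0=(2.0, 2.5),
            bounds=([1e-6, 1.0], [50.0, 8.0]),
            maxfev=10000,
        )
    se = float(np.sqrt(pcov[1, 1]))
    return float(popt[1]), 1.96 * se


def estimate_q10(
    frame: pd.DataFrame,
    months: tuple[int, ...] = (6, 7, 8),
    min_points: int = 30,
) -> Q10Result:
    """Q10 from a CI-weighted mean of monthly nighttime fits.

    For each calendar month/year with enough measured nighttime NEE the pair
    (r_c, q10) is fitted to NEE vs the blended temperature; the monthly q10
    values are combined as sum(w_i q_i)/sum(w_i) with w_i the inverse of the
    95% confidence-interval half width (Jacobian-based standard error).
    """
    ok = (frame["nee_flag"] == MEASURED) & np.isfinite(frame["nee"])
    ok &= frame["par"] < NIGHT_PAR_MAX
    ok &= np.isfinite(frame["t_air"]) & np.isfinite(frame["t_soil"])
    sub = frame.loc[ok & frame.index.month.isin(months)]

    monthly: list[Q10Estimate] = []
    for (year, month), grp in sub.groupby([sub.index.year, sub.index.month]):
        if len(grp) < min_points:
            continue
        t_sa = blended_temperature(grp["t_air"], grp["t_soil"])
        try:
            q10, ci = _fit_night_q10(np.asarray(t_sa), grp["nee"].to_numpy())
        except RuntimeError:
            continue
        if ci <= 0 or not np.isfinite(ci):
            continue
        monthly.append(Q10Estimate(q10=q10, ci_halfwidth=ci, year=int(year),
                                   month=int(month), n_points=len(grp)))
    if len(monthly) < 2:
        raise ValueError(
            f"q10 estimation needs >= 2 fittable months, got {len(monthly)}"
        )
    w = np.array([m.weight for m in monthly])
    q = np.array([m.q10 for m in monthly])
    return Q10Result(q10=float(np.sum(w * q) / np.sum(w)), monthly=monthly)


def estimate_theta(
    frame: pd.DataFrame,
    q10: float,
    candidates=None,
    months: tuple[int, ...] = (6, 7, 8),
    window_days: int = 15,
    min_points: int = 48,
    rmse_tol: float = 1e-6,
) -> float:
    """Curvature theta minimising summer NEE RMSE of the windowed fit.

    One-dimensional search over a grid in (0, 1]; ties and flat objectives
    resolve to the smaller candidate (first argmin on the ascending grid).
    A flat objective (RMSE range < rmse_tol) falls back to the 0.9 default
    with a warning.
    """
    if candidates is None:
        candidates = np.round(np.arange(0.05, 1.0001, 0.05), 3)
    summer = frame.loc[frame.index.month.isin(months)]
    scores = []
    for theta in candidates:
        try:
            fits = fit_all_windows(summer, q10, float(theta),
                                   window_days=window_days, min_points=min_points)
        except UnfittableWindowError:
            scores.append(np.inf)
            continue
        sq, n = 0.0, 0
        for p in fits:
            if p.rmse is None:
                continue
            sq += p.rmse**2 * p.n_points
            n += p.n_points
        scores.append(np.sqrt(sq / n) if n else np.inf)
    scores = np.asarray(scores)
    if not np.isfinite(scores).any():
        raise UnfittableWindowError("no candidate theta produced a fittable summer")
    if np.ptp(scores[np.isfinite(scores)]) < rmse_tol:
        warnings.warn("flat theta objective; falling back to default 0.9",
                      stacklevel=2)
        return THETA_DEFAULT
    return float(candidates[int(np.argmin(scores))])


def _refit_light_response(
    frame: pd.DataFrame, gpp_measured: pd.Series, base: PartitionParams
) -> PartitionParams:
    """Refit (alpha, p_max) of the NRH against partitioned GPP for gap-fill."""
    ok = np.isfinite(gpp_measured) & np.isfinite(frame["par"]) & np.isfinite(frame["t_air"])
    sub = frame.loc[ok]
    if len(sub) < 10:
        return base
    par = sub["par"].to_numpy()
    t_air = sub["t_air"].to_numpy()
    target = gpp_measured.loc[ok].to_numpy()

    def resid(x):
        p = replace(base, alpha=x[0], p_max=x[1])
        return gpp_light_response(par, t_air, p) - target

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.least_squares(
            resid, x0=(base.alpha, base.p_max),
            bounds=([1e-8, 1e-6], [0.2, 60.0]),
        )
    return replace(base, alpha=float(sol.x[0]), p_max=float(sol.x[1]))


def partition(
    frame: pd.DataFrame,
    window_fits: list[PartitionParams],
    refit_gapfill: bool = True,
) -> GPPSeries:
    """Partition NEE into respiration and GPP, gap-filling from the model.

    Measured rows: GPP = R(T_sa) - NEE, flag ``measured`` (noise-driven
    negative values are preserved, not clipped).  Missing rows: GPP from the
    light-response model, flag ``gapfilled``; by default alpha and p_max are
    refitted per window against the partitioned GPP before filling.
    """
    t_sa = pd.Series(
        blended_temperature(frame["t_air"], frame["t_soil"]), index=frame.index
    )
    gpp = pd.Series(np.nan, index=frame.index)
    resp = pd.Series(np.nan, index=frame.index)
    flag = pd.Series(MISSING, index=frame.index, dtype=object)

    for p in window_fits:
        if p.window is None:
            mask = pd.Series(True, index=frame.index)
        else:
            w0, w1 = p.window
            mask = (frame.index >= w0) & (frame.index < w1)
        if not mask.any():
            continue
        sub = frame.loc[mask]
        r = pd.Series(respiration(t_sa.loc[mask], p.r_c, p.q10), index=sub.index)
        resp.loc[mask] = r

        measured = (sub["nee_flag"] == MEASURED) & np.isfinite(sub["nee"]) & np.isfinite(r)
        gpp_meas = r.loc[measured] - sub.loc[measured, "nee"]
        gpp.loc[gpp_meas.index] = gpp_meas
        flag.loc[gpp_meas.index] = MEASURED

        fill_p = p
        if refit_gapfill and measured.sum() >= 10:
            fill_p = _refit_light_response(
                sub.loc[measured], gpp_meas, p
            )
        gaps = ~measured & np.isfinite(sub["par"]) & np.isfinite(sub["t_air"])
        if gaps.any():
            gsub = sub.loc[gaps]
            gpp.loc[gsub.index] = gpp_light_response(gsub["par"], gsub["t_air"], fill_p)
            flag.loc[gsub.index] = GAPFILLED

    return GPPSeries(method="NLR", gpp=gpp, flag=flag, resp=resp)
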
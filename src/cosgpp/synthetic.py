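"""Synthetic half-hourly flux and meteorology scenarios with known truth.

The generator emulates the canonical boreal-forest input table so every
estimator in the package can be exercised end-to-end against a known
ground truth:

* clear-sky PAR from solar geometry at the site latitude, attenuated by a
  daily beta-distributed cloudiness factor;
* air temperature with a seasonal trend and an afternoon-peaking diurnal
  cycle; soil temperature as a damped, lagged (exponentially smoothed)
  copy of air temperature;
* VPD from saturation vapour pressure and a stochastic relative-humidity
  process; soil water content as a slow reflected random walk;
* NEE = R - GPP with the Q10/non-rectangular-hyperbola truth parameters
  plus Gaussian noise;
* FCOS by inverting the COS proxy with a known truth LRU model, adding the
  constant soil flux and Gaussian noise (COS noise defaults are large
  relative to the signal, mirroring the poor 30-min signal-to-noise ratio
  of ecosystem COS measurements);
* block-structured missing-data masks with a configurable overall
  fraction (COS defaults to 48% gaps, i.e. 52% availability).

One seeded generator drives all randomness: a fixed seed reproduces the
series exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import FLAG_COLUMNS, MEASURED, MISSING
from .lru import LRUCapParams, lru_cap_from_field, lru_par
from .nlr_partition import PartitionParams, gpp_light_response, respiration

#: Hyytiala-like site latitude (degrees north)
LATITUDE_DEFAULT = 61.85


@dataclass
class SyntheticScenario:
    """Everything needed to reproduce one synthetic data set exactly."""

    start: str = "2017-05-01"
    end: str = "2017-07-31"          # inclusive
    latitude: float = LATITUDE_DEFAULT
    # truth partitioning parameters
    alpha: float = 0.03              # umol CO2 per umol photons
    p_max: float = 15.0              # umol m-2 s-1
    r_c: float = 2.0                 # umol m-2 s-1 at 0 degC
    q10: float = 2.2
    theta: float = 0.9
    t0: float = -2.0
    # truth LRU model
    lru_model: str = "cap"           # {"par", "cap", "const"}
    lru_const: float = 1.6
    cap_params: LRUCapParams = field(default_factory=LRUCapParams)
    # proxy constants
    co2_ppm: float = 415.0
    cos_ppt: float = 500.0
    soil_cos_flux: float = -2.7      # pmol m-2 s-1
    # noise (sd of additive Gaussian)
    sd_nee: float = 1.0              # umol m-2 s-1
    sd_fcos: float = 8.0             # pmol m-2 s-1
    # gaps
    gap_fraction_nee: float = 0.3
    gap_fraction_fcos: float = 0.48  # 52% availability
    mean_gap_halfhours: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_nee < 0 or self.sd_fcos < 0:
            raise ValueError("noise sds must be non-negative")
        for frac in (self.gap_fraction_nee, self.gap_fraction_fcos):
            if not 0.0 <= frac < 1.0:
                raise ValueError("gap fractions must be in [0, 1)")
        if self.lru_model not in {"par", "cap", "const"}:
            raise ValueError(f"unknown lru_model {self.lru_model!r}")

    @property
    def partition_params(self) -> PartitionParams:
        return PartitionParams(
            alpha=self.alpha, p_max=self.p_max, r_c=self.r_c,
            q10=self.q10, theta=self.theta, t0=self.t0,
        )


def _solar_elevation_sin(index: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """sin(solar elevation), clipped at 0, for a simple clear-sky PAR model."""
    doy = index.dayofyear.to_numpy()
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (doy + 10) / 365.25)
    lat = np.deg2rad(latitude)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    s = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return np.maximum(s, 0.0)


def generate_met(scenario: SyntheticScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Half-hourly meteorology for the scenario period."""
    index = pd.date_range(
        pd.Timestamp(scenario.start),
        pd.Timestamp(scenario.end) + pd.Timedelta(hours=23, minutes=30),
        freq="30min",
    )
    n = len(index)
    doy = index.dayofyear.to_numpy()
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0

    # PAR: clear sky x daily cloudiness (beta-distributed attenuation)
    sin_el = _solar_elevation_sin(index, scenario.latitude)
    n_days = int(np.ceil(n / 48))
    cloud_daily = rng.beta(4.0, 1.5, size=n_days)  # mean 0.727, realistic spread
    cloud = np.repeat(cloud_daily, 48)[:n]
    par = 2000.0 * sin_el * cloud

    # air temperature: seasonal trend + afternoon-peaking diurnal cycle + AR noise
    seasonal = 11.0 + 7.0 * np.sin(2 * np.pi * (doy - 110) / 365.25)
    diurnal = 4.5 * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    ar = np.empty(n)
    ar[0] = 0.0
    eps = rng.normal(0.0, 0.35, size=n)
    for i in range(1, n):
        ar[i] = 0.97 * ar[i - 1] + eps[i]
    t_air = seasonal + diurnal + ar

    # soil temperature: damped, lagged air temperature (2-day e-folding)
    t_soil = pd.Series(t_air, index=index).ewm(halflife="48h", times=index).mean()
    t_soil = 0.75 * t_soil.to_numpy() + 2.0

    # VPD from Magnus saturation pressure and a stochastic RH process
    es = 0.6108 * np.exp(17.27 * t_air / (t_air + 237.3))  # kPa
    rh = np.clip(0.92 - 0.25 * par / 1800.0 + 0.05 * np.tanh(ar / 3.0), 0.3, 1.0)
    vpd = np.maximum(es * (1.0 - rh), 0.0)

    # SWC: slow reflected random walk within [0.15, swc_sat]
    lo, hi = 0.15, scenario.cap_params.swc_sat
    steps = rng.normal(0.0, 2.5e-4, size=n)
    swc = np.empty(n)
    swc[0] = 0.28
    for i in range(1, n):
        v = swc[i - 1] + steps[i]
        if v < lo:
            v = 2 * lo - v
        elif v > hi:
            v = 2 * hi - v
        swc[i] = v

    # u*: lognormal scatter around the filter threshold at night (roughly
    # half of calm nights are rejected, as at real towers) plus a daytime
    # convective boost
    ustar = rng.lognormal(np.log(0.29), 0.5, size=n) + 0.15 * par / 1800.0

    return pd.DataFrame(
        {
            "ustar": ustar,
            "t_air": t_air,
            "t_soil": t_soil,
            "par": par,
            "vpd": vpd,
            "swc": swc,
            "co2_ppm": scenario.co2_ppm,
            "cos_ppt": scenario.cos_ppt,
        },
        index=index,
    ).rename_axis("timestamp")


def true_lru(met: pd.DataFrame, scenario: SyntheticScenario) -> np.ndarray:
    """Truth LRU per row; NaN where undefined (dark periods)."""
    if scenario.lru_model == "par":
        return np.asarray(lru_par(met["par"]), dtype=float)
    if scenario.lru_model == "cap":
        return np.asarray(
            lru_cap_from_field(met["par"], met["vpd"], met["swc"],
                               scenario.cap_params),
            dtype=float,
        )
    return np.full(len(met), scenario.lru_const)


def generate_fluxes(
    met: pd.DataFrame, scenario: SyntheticScenario, rng: np.random.Generator
) -> pd.DataFrame:
    """NEE and FCOS (with truth columns) from the met series.

    NEE = R_true - GPP_true + noise.  The canopy COS flux inverts the proxy
    relation, -GPP * LRU * [COS]_a/[CO2]_a (pmol m-2 s-1 for GPP in
    umol m-2 s-1), then the soil flux and noise are added to form the
    ecosystem flux.  Where the truth LRU is undefined (dark) the canopy
    uptake is zero, consistent with zero GPP.
    """
    p = scenario.partition_params
    t_sa = (met["t_air"].to_numpy() + met["t_soil"].to_numpy()) / 2.0
    gpp_true = np.asarray(gpp_light_response(met["par"], met["t_air"], p))
    r_true = np.asarray(respiration(t_sa, p.r_c, p.q10))
    nee = r_true - gpp_true + rng.normal(0.0, scenario.sd_nee, size=len(met))

    lru_true = true_lru(met, scenario)
    fcos_canopy = np.where(
        np.isfinite(lru_true) & (gpp_true > 0),
        -gpp_true * lru_true * scenario.cos_ppt / scenario.co2_ppm,
        0.0,
    )
    fcos = fcos_canopy + scenario.soil_cos_flux + rng.normal(
        0.0, scenario.sd_fcos, size=len(met)
    )

    out = met.copy()
    out.insert(0, "fcos", fcos)
    out.insert(0, "nee", nee)
    out["nee_flag"] = MEASURED
    out["fcos_flag"] = MEASURED
    out["gpp_true"] = gpp_true
    out["resp_true"] = r_true
    out["lru_true"] = lru_true
    out["fcos_canopy_true"] = fcos_canopy
    return out


def apply_gaps(
    frame: pd.DataFrame,
    rng: np.random.Generator,
    column: str,
    fraction: float,
    mean_block_halfhours: float = 6.0,
) -> pd.DataFrame:
    """Punch block-structured gaps into one flux column (flag ``missing``).

    Blocks start uniformly at random with geometric lengths of the given
    mean; blocks accumulate until the overall missing fraction reaches the
    target.  Deterministic for a given generator state.
    """
    if fraction <= 0:
        return frame
    out = frame.copy()
    n = len(out)
    target = int(round(fraction * n))
    missing = np.zeros(n, dtype=bool)
    p_geom = min(1.0, 1.0 / mean_block_halfhours)
    guard = 0
    while missing.sum() < target and guard < 100 * n:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(p_geom))
        missing[start:start + length] = True
        guard += 1
    # trim overshoot so the realised fraction matches the request closely
    excess = missing.sum() - target
    if excess > 0:
        on = np.flatnonzero(missing)
        missing[on[rng.choice(len(on), size=excess, replace=False)]] = False
    out.loc[missing, column] = np.nan
    out.loc[missing, f"{column}_flag"] = MISSING
    return out


def generate(scenario: SyntheticScenario) -> pd.DataFrame:
    """Full scenario: met + fluxes + gap masks, with truth columns retained.

    The returned frame carries the canonical observation columns (the
    synthetic "measurements") alongside ``gpp_true``, ``resp_true``,
    ``lru_true`` and ``fcos_canopy_true``.
    """
    rng = np.random.default_rng(scenario.seed)
    met = generate_met(scenario, rng)
    frame = generate_fluxes(met, scenario, rng)
    frame = apply_gaps(frame, rng, "nee", scenario.gap_fraction_nee,
                       scenario.mean_gap_halfhours)
    frame = apply_gaps(frame, rng, "fcos", scenario.gap_fraction_fcos,
                       scenario.mean_gap_halfhours)
    return frame


TRUTH_COLUMNS = ["gpp_true", "resp_true", "lru_true", "fcos_canopy_true"]


def split_truth(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate the observation table from the truth columns."""
    obs = frame.drop(columns=[c for c in TRUTH_COLUMNS if c in frame.columns])
    truth = frame[[c for c in TRUTH_COLUMNS if c in frame.columns]].copy()
    return obs, truth
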
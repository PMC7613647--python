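"""Leaf relative uptake (LRU) models for the COS proxy of GPP.

LRU is the ratio of normalised COS to CO2 deposition velocities at the
leaf.  Three formulations are provided:

* an empirical PAR relation, ``LRU = 607.26 / PAR + 0.57`` (PAR in
  umol m-2 s-1), derived from branch-chamber flux measurements;
* the general diffusive form in boundary-layer, stomatal and mesophyll
  conductances with the CO2:COS diffusivity ratios 1.21 (stomata) and 1.14
  (boundary layer), and its infinite-conductance reduction
  ``LRU = 1 / (1.21 (1 - ci/ca))``;
* the CAP formulation, in which stomatal conductance optimises leaf
  photosynthesis against non-stomatal limitations tied to leaf water
  potential.  The resulting intercellular CO2 gives

      LRU_CAP = (1/1.21) * ca/(ca - Gamma*)
                * [1 + (Ksl |psi_c|)/(1.6 gc VPD) * (1 + 2 Gamma* gc / (alpha PAR))]

  with PAR in mol m-2 s-1 and VPD in mol mol-1, and Ksl the soil-to-leaf
  hydraulic conductance assembled from a soil (Campbell retention curve,
  root geometry) and a xylem pathway in series.

The physiological constants default to literature values for a boreal
Scots-pine stand; the composite parameters X = |psi_c|/(1.6 gc) and
Y = 2 Gamma* gc / alpha summarise the fittable sensitivity of LRU_CAP and
evaluate to X = 2.5 MPa m2 s mol-1 and Y = 0.001 mol m-2 s-1 at defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

#: CO2:COS conductance ratio for stomata
RATIO_STOMATA = 1.21
#: CO2:COS conductance ratio for the leaf boundary layer
RATIO_BOUNDARY = 1.14

#: standard sea-level barometric pressure (kPa) for VPD kPa -> mol mol-1
PRESSURE_KPA = 101.325
#: PAR floor (umol m-2 s-1) below which LRU is left undefined (1/PAR blow-up)
PAR_FLOOR_UMOL = 10.0

#: empirical PAR-relation coefficients (PAR in umol m-2 s-1)
LRU_PAR_SLOPE = 607.26
LRU_PAR_ASYMPTOTE = 0.57


@dataclass(frozen=True)
class LRUCapParams:
    """Physiological and soil-hydraulic constants of the CAP LRU model.

    Attributes
    ----------
    c_a : mol mol-1
        Atmospheric CO2 molar mixing ratio.
    gamma_star : mol mol-1
        CO2 photorespiratory compensation point (fixed growing-season value).
    g_c : mol m-2 s-1
        Carboxylation conductance in the absence of non-stomatal limitations.
    psi_c : MPa
        Critical leaf water potential at which non-stomatal limitations shut
        photosynthesis down (negative).
    alpha_q : mol mol-1
        Photosynthetic quantum yield.
    k_x : mol m-2 s-1 MPa-1
        Leaf-specific root-to-leaf xylem hydraulic conductance.
    k_soil_sat : mol m-1 s-1 MPa-1
        Saturated soil hydraulic conductivity (rooting-zone horizon).
    r1 : m-1
        Root length index.
    lai : m2 m-2
        All-sided leaf area index.
    r_cyl, r_root : m
        Radius of the soil cylinder accessible to a root and the fine-root
        radius (their log ratio sets the rhizosphere geometry factor).
    swc_sat : m3 m-3
        Saturation soil water content.
    b : dimensionless
        Campbell water-retention exponent.
    """

    c_a: float = 415e-6
    gamma_star: float = 50e-6
    g_c: float = 0.5
    psi_c: float = -2.0
    alpha_q: float = 0.05
    k_x: float = 0.78e-3
    k_soil_sat: float = 5.7
    r1: float = 5300.0
    lai: float = 8.0
    r_cyl: float = 0.00458
    r_root: float = 0.3e-3
    swc_sat: float = 0.52
    b: float = 4.46

    def __post_init__(self) -> None:
        if self.psi_c >= 0:
            raise ValueError("psi_c must be negative (a water potential)")
        for name in ("c_a", "gamma_star", "g_c", "alpha_q", "k_x",
                     "k_soil_sat", "r1", "lai", "r_cyl", "r_root",
                     "swc_sat", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c_a <= self.gamma_star:
            raise ValueError("c_a must exceed gamma_star")
        if self.r_cyl <= self.r_root:
            raise ValueError("r_cyl must exceed r_root")

    @property
    def x(self) -> float:
        """Composite X = |psi_c| / (1.6 g_c), MPa m2 s mol-1."""
        return abs(self.psi_c) / (1.6 * self.g_c)

    @property
    def y(self) -> float:
        """Composite Y = 2 Gamma* g_c / alpha, mol m-2 s-1."""
        return 2.0 * self.gamma_star * self.g_c / self.alpha_q

    @property
    def lru_floor(self) -> float:
        """High-light, high-VPD asymptote (1/1.21) ca/(ca - Gamma*)."""
        return (1.0 / RATIO_STOMATA) * self.c_a / (self.c_a - self.gamma_star)


def lru_par(par):
    """Empirical LRU from PAR (umol m-2 s-1); undefined (NaN) for PAR <= 0."""
    par = np.asarray(par, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = LRU_PAR_SLOPE / par + LRU_PAR_ASYMPTOTE
    return np.where(par > 0, out, np.nan)


def lru_general(gb_cos, gs_cos, gm_cos, ci_over_ca):
    """General diffusive LRU from the three COS conductances and ci/ca.

    LRU = [1/(1 - ci/ca)] * [1/1.21 + (1/1.14)(gs/gb)] / [1 + gs/gb + gs/gm]

    ``np.inf`` is accepted for any conductance (the corresponding ratio
    vanishes).  ci/ca >= 1 is rejected: the draw-down must be positive.
    """
    gb = np.asarray(gb_cos, dtype=float)
    gs = np.asarray(gs_cos, dtype=float)
    gm = np.asarray(gm_cos, dtype=float)
    r = np.asarray(ci_over_ca, dtype=float)
    if np.any(r >= 1.0):
        raise ValueError("ci/ca must be < 1")
    if np.any(gb <= 0) or np.any(gs <= 0) or np.any(gm <= 0):
        raise ValueError("conductances must be positive")
    with np.errstate(divide="ignore"):
        sb = np.where(np.isinf(gb), 0.0, gs / gb)
        sm = np.where(np.isinf(gm), 0.0, gs / gm)
    num = 1.0 / RATIO_STOMATA + sb / RATIO_BOUNDARY
    den = 1.0 + sb + sm
    return (1.0 / (1.0 - r)) * num / den


def lru_infinite_conductance(ci_over_ca):
    """LRU with infinite boundary-layer and mesophyll conductances."""
    r = np.asarray(ci_over_ca, dtype=float)
    if np.any(r >= 1.0) or np.any(r < 0):
        raise ValueError("ci/ca must be in [0, 1)")
    return 1.0 / (RATIO_STOMATA * (1.0 - r))


def soil_hydraulic_conductivity(swc, params: LRUCapParams = LRUCapParams()):
    """Campbell-form soil hydraulic conductivity (mol m-1 s-1 MPa-1).

    k_soil = k_soil_sat * (SWC / SWC_sat)^(2b + 3); SWC above saturation is
    clamped to the saturated value with a warning.
    """
    swc = np.asarray(swc, dtype=float)
    if np.any(swc > params.swc_sat):
        warnings.warn("SWC above saturation clamped to SWC_sat", stacklevel=2)
        swc = np.minimum(swc, params.swc_sat)
    with np.errstate(invalid="ignore"):
        out = params.k_soil_sat * np.power(swc / params.swc_sat, 2.0 * params.b + 3.0)
    return np.where(swc > 0, out, np.nan)


def soil_to_leaf_conductance(swc, params: LRUCapParams = LRUCapParams()):
    """Leaf-specific soil-to-leaf hydraulic conductance (mol m-2 s-1 MPa-1).

    The soil pathway K_soil = (R1/LAI) * 2 pi k_soil / ln(r_cyl/r_root)
    combines in series with the xylem pathway K_X:
    K_sl = K_soil K_X / (K_soil + K_X).  Wet soil makes K_soil huge, so
    K_sl -> K_X; dry soil collapses K_sl to zero.
    """
    k_soil = soil_hydraulic_conductivity(swc, params)
    geom = (params.r1 / params.lai) * 2.0 * np.pi / np.log(params.r_cyl / params.r_root)
    k_soil_leaf = geom * k_soil
    return k_soil_leaf * params.k_x / (k_soil_leaf + params.k_x)


def lru_cap(par, vpd, swc, params: LRUCapParams = LRUCapParams()):
    """CAP-theory LRU in SI units: PAR in mol m-2 s-1, VPD in mol mol-1.

    Strictly decreasing in PAR and in VPD, increasing in soil wetness, and
    bounded below by ``params.lru_floor``.  Non-positive PAR or VPD yields
    NaN (dark or saturated air leaves LRU undefined).
    """
    par = np.asarray(par, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    k_sl = soil_to_leaf_conductance(swc, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = 1.0 + (params.x * k_sl / vpd) * (1.0 + params.y / par)
        out = params.lru_floor * bracket
    return np.where((par > 0) & (vpd > 0), out, np.nan)


def lru_cap_from_field(
    par_umol,
    vpd_kpa,
    swc,
    params: LRUCapParams = LRUCapParams(),
    pressure_kpa: float = PRESSURE_KPA,
    par_floor_umol: float = PAR_FLOOR_UMOL,
):
    """CAP LRU from field units (PAR umol m-2 s-1, VPD kPa).

    PAR below ``par_floor_umol`` is masked to avoid the 1/PAR blow-up; the
    proxy conversion is only meaningful in daylight anyway.
    """
    par_umol = np.asarray(par_umol, dtype=float)
    out = lru_cap(par_umol * 1e-6, np.asarray(vpd_kpa, dtype=float) / pressure_kpa,
                  swc, params)
    return np.where(par_umol >= par_floor_umol, out, np.nan)


def lru_cap_xy(par, vpd, swc, x: float, y: float,
               params: LRUCapParams = LRUCapParams()):
    """CAP LRU parameterised directly by the composites (X, Y), SI units."""
    par = np.asarray(par, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    k_sl = soil_to_leaf_conductance(swc, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = 1.0 + (x * k_sl / vpd) * (1.0 + y / par)
        out = params.lru_floor * bracket
    return np.where((par > 0) & (vpd > 0), out, np.nan)


def fit_xy(par, vpd, swc, lru_obs, params: LRUCapParams = LRUCapParams()):
    """Fit the composites (X, Y) of the CAP model to observed LRU.

    All other parameters stay fixed; the fit is plain least squares on LRU
    residuals.  Requires >= 10 observations spanning a PAR range (a single
    PAR level cannot separate X from Y).

    Returns
    -------
    (x, y, rmse) : fitted composites and the root-mean-square LRU residual.
    """
    par = np.asarray(par, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    swc = np.asarray(swc, dtype=float)
    lru_obs = np.asarray(lru_obs, dtype=float)
    ok = np.isfinite(par) & np.isfinite(vpd) & np.isfinite(swc) & np.isfinite(lru_obs)
    ok &= (par > 0) & (vpd > 0)
    par, vpd, swc, lru_obs = par[ok], vpd[ok], swc[ok], lru_obs[ok]
    if par.size < 10:
        raise ValueError(f"need >= 10 usable observations, got {par.size}")
    if np.ptp(par) < 1e-12 * max(np.max(np.abs(par)), 1e-300):
        raise ValueError("degenerate PAR range: Y is unidentifiable")

    def resid(xy):
        return lru_cap_xy(par, vpd, swc, xy[0], xy[1], params) - lru_obs

    sol = optimize.least_squares(
        resid, x0=(params.x, params.y), bounds=([1e-8, 1e-12], [1e3, 1.0])
    )
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return float(sol.x[0]), float(sol.x[1]), rmse
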
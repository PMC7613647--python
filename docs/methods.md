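# Methods

This note documents the models implemented in `cosgpp`, their
assumptions, the tunable parameters, the synthetic data the test suite
runs on, and the numerical and design choices that were genuinely open.

## Data model and filtering

All estimators consume one validated half-hourly table (strict 30-min
grid, local standard time, no DST). Fluxes carry provenance flags
(`measured` / `gapfilled` / `missing`); a value flagged missing never
reaches a fit or a mean. Sign conventions: NEE positive upward
(emission), GPP positive, COS flux negative for uptake.

Low-turbulence periods are removed with a friction-velocity filter
(default threshold 0.3 m s⁻¹ applied to the whole record). The rule is a
strict `<`: a half hour with u* exactly at the threshold is retained.
Rows with unknown u* are rejected as unverifiable. The filter only erases
flux values and flags — it never alters numbers — so it is idempotent.
Measured fluxes are filtered before any gap-filling.

## NEE partitioning (NLR)

* Respiration: `R = R_c · Q10^(T_sa/10)` with `T_sa` the arithmetic mean
  of air temperature at reference height and shallow soil temperature —
  a blend that tracks the ecosystem's mixed respiring biomass better than
  either temperature alone. An air-temperature-only driver is a
  one-argument variant, not a separate method.
* GPP: non-rectangular hyperbola in PAR (initial slope α, asymptote
  P_max, curvature Θ ∈ (0, 1]) times the sigmoid gate
  `f(T_a) = 1/(1 + exp(2(T₀ − T_a)))`, T₀ = −2 °C, which drives GPP to
  zero at freezing temperatures. The discriminant uses the standard form
  `(αI + P_max)² − 4Θ·αI·P_max`; with α included the expression is
  dimensionally consistent and reduces continuously to the rectangular
  hyperbola `αI·P_max/(αI + P_max)` as Θ → 0 (switched below Θ = 10⁻⁹).
* Window fitting: (α, P_max, R_c) minimise squared NEE residuals over
  consecutive non-overlapping 15-day windows anchored at 1 January, with
  Q10 and Θ held fixed. Bounded nonlinear least squares
  (α ∈ (0, 0.2], P_max ∈ (0, 60], R_c ∈ (0, 20] µmol m⁻² s⁻¹) from the
  fixed start point (0.03, 15, 2), so fits are deterministic. A window
  needs ≥ 48 measured half hours including some nighttime (PAR < 10
  µmol m⁻² s⁻¹) coverage — R_c is identified only by dark data; windows
  failing this are filled by linear interpolation of neighbouring fits
  (nearest fit carried over at the edges). Parameters apply stepwise, with
  no interpolation between fittable windows.
* Q10: per calendar month of the summer season, (R_c, Q10) are fitted to
  nighttime NEE against T_sa; monthly values combine as
  `Σ wᵢqᵢ / Σ wᵢ` with `wᵢ = 1/CIᵢ`, where CIᵢ is the 95 % half width
  from the Jacobian-based standard error of the fit. The combined CI
  half width propagates the monthly CIs through the weighted mean
  assuming independent months. At least two fittable months are required.
* Θ: one-dimensional grid search (default step 0.05 on (0, 1]); each
  candidate re-runs the full summer windowed fit and is scored by pooled
  NEE RMSE. Ties and flat objectives resolve to the smaller candidate; an
  entirely flat objective falls back to 0.9 with a warning.
* Partitioning: on measured rows `GPP = R − NEE`; nighttime noise can
  make this negative and the negative values are preserved — clipping
  would bias every downstream average. Gaps are filled from the light
  response with (α, P_max) refitted per window against the partitioned
  GPP itself, so the fill model is anchored to the partitioned quantity
  rather than to raw NEE.

## COS proxy

The soil's COS uptake (default −2.7 pmol m⁻² s⁻¹, constant — its diurnal
variation at this kind of site is below 1 pmol m⁻² s⁻¹, so averaging
costs little) is subtracted from the ecosystem flux; the canopy flux then
converts via `GPP = −F_canopy/LRU · [CO₂]ₐ/[COS]ₐ`. The concentration
ratio is taken as the ratio of the measured mixing ratios, exact when
both species share the measurement-height temperature and pressure.

COS gap-filling fits `F = −(a·PAR/(PAR + b))/(1 + c·VPD) + d` — a
saturating radiation response attenuated by atmospheric dryness with a
nocturnal offset — per 15-day window when ≥ 200 measured points are
available, else series-wide. The functional form is pluggable; this
default encodes the drivers (PAR, VPD) that empirical COS gap-filling
uses without committing to any site-specific shape.

### LRU models

* Empirical: `LRU = 607.26/PAR + 0.57` (PAR in µmol m⁻² s⁻¹), from
  branch-chamber measurements at the top of a pine canopy; undefined in
  the dark.
* General diffusive form:
  `LRU = [1/(1 − cᵢ/cₐ)] · [1/1.21 + (1/1.14)(gs/gb)] / [1 + gs/gb + gs/gm]`
  with 1.21 and 1.14 the CO₂:COS diffusivity ratios for stomata and
  boundary layer. With gb, gm → ∞ this reduces to
  `1/(1.21(1 − cᵢ/cₐ))`.
* CAP: substituting the stomatal-optimization solution for cᵢ gives the
  closed form in the README. Γ* (50×10⁻⁶ mol mol⁻¹) and the quantum
  yield α (0.05 mol mol⁻¹) are fixed growing-season values; no
  temperature response is implemented. The soil-to-leaf conductance
  chain is `k_soil = k_sat(SWC/SWC_sat)^(2b+3)` (Campbell),
  `K_soil = (R₁/LAI)·2π·k_soil/ln(r_cyl/r_root)` (natural logarithm, the
  standard choice in the soil-root resistance literature; configurable),
  and `K_sl = K_soil·K_X/(K_soil + K_X)` in series with the xylem. The
  grouping of the K_soil expression is the one that yields
  mol m⁻² s⁻¹ MPa⁻¹. Wet soil makes K_sl ≈ K_X; dry soil collapses it.
* The composites `X = |ψ_c|/(1.6 g_c)` and `Y = 2Γ* g_c/α` fully
  parameterise the CAP sensitivity and can be fitted to observed LRU
  (`fit_xy`, plain least squares on LRU residuals, RMSE reported as the
  root mean square of those residuals). Package defaults are the
  literature values (X = 2.5, Y = 0.001), not fitted ones: the model's
  portability rests on literature parameterisation, and fitting is a
  sensitivity diagnostic.
* LRU is computed only above a PAR floor (default 10 µmol m⁻² s⁻¹) to
  avoid the 1/PAR blow-up. For cumulative sums the dark periods are
  assigned zero GPP flagged `gapfilled` — photosynthesis is zero in the
  dark regardless of the undefined LRU — while measured-only comparisons
  automatically exclude them. VPD is stored in kPa and converted to
  mol mol⁻¹ inside the CAP formula with a configurable barometric
  pressure (default 101.325 kPa).

## Aggregation and comparison protocol

* Daily mean: exists iff strictly more than 50 % of the 48 half hours
  are *measured*; the mean then uses all available values (measured and
  gap-filled). The count rule keeps daily estimates anchored to
  measurements; using the filled values in the mean avoids a
  time-of-day sampling bias.
* Monthly mean: unweighted mean of available daily means.
* Diurnal composites: per-month medians per half-hour-of-day on the
  common mask of all compared series (gap-filled values included);
  months at or below 55 % common coverage are excluded (strict rule).
* Cumulative GPP: `Σ GPP · 1800 s · 12.011×10⁻⁶ gC µmol⁻¹` over the
  period; requires a complete gap-filled series (a partial sum is not a
  total) and reports the gap-filled fraction alongside.
* Binned responses: measured-only common mask, equal-count bins by
  driver order (remainder spread so sizes differ by ≤ 1, larger bins
  first); for non-PAR drivers rows with PAR ≤ 700 µmol m⁻² s⁻¹ are
  dropped first to decouple the driver from radiation.
* Method comparison: common measured mask, then aggregation to the
  requested timescale; median relative difference (with quartiles)
  against a designated reference, and a plain one-way ANOVA with method
  as the single factor, treating aggregated cells as independent
  replicates (no repeated-measures correction — the simplest reading of
  an unadorned ANOVA across methods). Identical groups short-circuit to
  F = 0, p = 1.

## Synthetic scenarios

The generator emulates a boreal summer at 61.85° N: clear-sky PAR from
solar geometry times a daily beta-distributed cloudiness (July means fall
in the 300–600 µmol m⁻² s⁻¹ band); air temperature with seasonal trend,
afternoon-peaking diurnal cycle and AR(1) weather noise; soil temperature
as a damped 2-day exponential smoothing of air temperature; VPD from
Magnus saturation pressure and a radiation-linked stochastic RH; SWC as a
slow reflected random walk in [0.15, SWC_sat]; u* lognormal around the
filter threshold at night (roughly half of calm nights are rejected, as
at real towers) with a daytime convective boost.

Fluxes follow the forward models exactly: NEE = R_true − GPP_true plus
Gaussian noise (default sd 1 µmol m⁻² s⁻¹), and FCOS by inverting the
proxy relation with a chosen truth LRU model (CAP by default), constant
mixing ratios (415 ppm CO₂, 500 ppt COS), the constant soil flux, and
Gaussian noise whose default (8 pmol m⁻² s⁻¹) is large relative to the
~20 pmol signal, mirroring the poor 30-min signal-to-noise of real
ecosystem COS measurements. Gaps are punched in blocks (geometric
lengths, mean 6 half hours) to a target fraction — 30 % on NEE and 48 %
on FCOS (52 % availability) by default. All randomness flows through one
seeded generator; a fixed seed reproduces the table byte-for-byte.

What the generator does *not* emulate: storage and advection terms,
footprint variability, instrument spikes, seasonal phenology of the
light-response parameters (truth parameters are constant over the
scenario), temperature dependence of Γ* and α, or diurnal soil COS flux
variation. Passing tests therefore demonstrate correctness of the
estimators under their own assumptions and realistic noise/gap
structure, not robustness to the structural mismatches of field data.

## Problem sizes and determinism

Recovery tests and the acceptance script use single May–July summers
(4 416 half hours) and 8–20 replicates — enough for median biases well
inside the 5 % acceptance band while keeping the whole suite in seconds.
All optimiser starts are fixed constants; the only randomness is the
scenario seed, so every reported number is exactly reproducible.

## Known limitations

* The CAP variant with finite mesophyll conductance is not implemented;
  only the general conductance-ratio form is available for exploring
  finite-gm behaviour.
* The Θ search is a grid, not a continuous optimisation; its resolution
  bounds the recoverable curvature.
* The ANOVA treats half hours (or days) as independent, ignoring serial
  correlation; its p-values are optimistic on autocorrelated data.
* Kernel-density diagnostics of GPP distributions are intentionally
  left out; histograms of the daily means serve that purpose.
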
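# cosgpp

Estimation of ecosystem gross primary production (GPP) from half-hourly
eddy-covariance data, using both CO₂ and carbonyl sulfide (COS) fluxes.

Eddy covariance measures only the *net* ecosystem CO₂ exchange
(NEE = R − GPP), so photosynthesis must be inferred. This package
implements, as one consistent toolkit, the two main routes:

1. **Flux partitioning (NLR)** — ecosystem respiration is modelled as a
   Q10 exponential of a blended air/soil temperature,
   `R = R_c · Q10^(T_sa/10)`, fitted to nighttime data; GPP follows a
   non-rectangular hyperbola of PAR with a sigmoidal low-temperature gate,

   `GPP = [αI + P_max − √((αI + P_max)² − 4Θ·αI·P_max)] · f(T_a) / (2Θ)`,

   with `f(T_a) = 1/(1 + e^{2(T₀ − T_a)})`, T₀ = −2 °C. Parameters
   (α, P_max, R_c) are fitted per 15-day window; Q10 is a CI-weighted mean
   of monthly nighttime fits; Θ is picked by a summer-wide RMSE search.

2. **COS proxy** — COS diffuses into leaves through the same stomatal
   pathway as CO₂ and is destroyed by carbonic anhydrase, so after
   subtracting the soil COS flux the canopy flux converts to GPP through
   the leaf relative uptake ratio (LRU):

   `GPP = −F_COS / LRU · [CO₂]ₐ / [COS]ₐ`.

   Two LRU models are provided: an empirical radiation relation,
   `LRU = 607.26/PAR + 0.57`, and a stomatal-optimization (CAP)
   formulation in which the intercellular CO₂ follows from maximizing
   photosynthesis against water-potential-driven non-stomatal limitations:

   `LRU_CAP = (1/1.21)·c_a/(c_a − Γ*) · [1 + K_sl·|ψ_c|/(1.6·g_c·VPD) · (1 + 2Γ*·g_c/(α·PAR))]`,

   where `K_sl` is the soil-to-leaf hydraulic conductance built from a
   Campbell retention curve, root geometry and a xylem conductance. At the
   default literature parameters for a boreal Scots-pine stand the
   composite sensitivities are `X = |ψ_c|/(1.6 g_c) = 2.5 MPa m² s mol⁻¹`
   and `Y = 2Γ* g_c/α = 0.001 mol m⁻² s⁻¹`.

On top sit the aggregation and comparison rules used to confront the
methods (strict >50 % measured-data rule for daily means, >55 % coverage
rule for diurnal composites, May–July cumulative sums in gC m⁻²,
equal-count binned environmental responses, common-mask median differences
and one-way ANOVA), and a **synthetic scenario generator** that produces
half-hourly meteorology, NEE and COS fluxes from known ground truth so
every estimator can be validated end-to-end.

Intended users: flux-tower scientists and ecophysiology modellers working
with FLUXNET-style half-hourly CSV data who want reproducible, testable
GPP estimates and method intercomparisons.

## Worked example

```python
from cosgpp import (SyntheticScenario, generate, split_truth,
                    run_pipeline, cumulative_gpp, lru_par, lru_cap_from_field)

# LRU models at midday conditions (PAR 1000 umol m-2 s-1, VPD 1 kPa, SWC 0.28)
print(float(lru_par(1000.0)))                        # 1.17726
print(float(lru_cap_from_field(1000.0, 1.0, 0.28)))  # 1.3109271518350751

# one synthetic May-July summer with known truth, noise and gaps
scn = SyntheticScenario(seed=42)
obs, truth = split_truth(generate(scn))
result = run_pipeline(obs.reset_index())
print(round(result.q10, 3))                          # 2.211  (truth: 2.2)
for label, series in result.series.items():
    c = cumulative_gpp(series, scn.start, scn.end)
    print(label, round(c.total_gc_m2, 1))
# NLR 765.3, COS_PAR 1200.0, COS_CAP 754.3  (truth: 765.2 gC m-2)
for pair in result.reports["daily"].pairs:
    print(pair.method, round(pair.median_relative_pct, 1))
# COS_PAR +54.8 %, COS_CAP -1.3 %  vs NLR, daily scale
```

The synthetic COS fluxes here were generated with the CAP LRU as truth,
so decoding with the same model (COS_CAP) agrees with the partitioned and
true GPP to about a percent, while decoding with the empirical PAR
relation (COS_PAR) overestimates strongly at high radiation — the LRU
curves cross, and midday GPP inherits the ratio of the two LRUs.

A command-line interface mirrors the library:

```sh
cosgpp synth --seed 42 --out synth.csv
cosgpp partition-nlr synth.csv --out gpp_nlr.csv --params-out params.yaml
cosgpp gpp-cos synth.csv --lru cap --out gpp_cos_cap.csv
cosgpp run synth.csv --out-prefix demo
```

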
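# Methods

This note records the models implemented in `maizegxe`, the defaults and
the reasoning behind the genuinely open design choices. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Crop simulator

### Phenology

Development is driven by thermal time, GDD = max(0, (Tmax+Tmin)/2 − Tbase)
with Tbase = 8 °C for maize. An optional DSSAT-style cap (optimum 34 °C,
ceiling 44 °C, `tt_cap=True`) never increases the daily value; it is off by
default because the plain clamped-mean form is the reference definition,
while supra-optimal effects are normally carried by the temperature
response curves (below).

Stages and their durations:

| stage | duration | source |
|---|---|---|
| sowing → emergence | 45 °C d | fixed default (emergence thermal time is rarely reported; 45 °C d ≈ 3 days at savanna temperatures) |
| emergence → end juvenile | P1 °C d | cultivar coefficient |
| end juvenile → tassel initiation | ≥ 4 days, lengthened by P2·max(0, daylength − 12.5 h) | photoperiod induction; daily rate 1/(4 + delay) accumulated to 1 |
| tassel initiation → anthesis | (5 + P1/24)·PHINT °C d | remaining-leaf appearance |
| silking → physiological maturity | P5 °C d | cultivar coefficient |

The leaf rule is the one genuinely free constant: total leaves still to
appear after the juvenile phase are a basal 5 plus one leaf initiated per
24 °C d of juvenile phase (a plastochron of roughly half the phyllochron).
The pair (5, 24) was fixed once so that, under a standard savanna profile
(31/22 °C), the 16 packaged varieties span ≈ 43–66 days to anthesis and
their maturity-group means order strictly extra-early < early <
intermediate < late. Note that no anthesis rule that is increasing in both
P1 and PHINT can order every *individual* pair across adjacent groups
(some intermediate varieties have a longer phyllochron than some late
ones), so group means are the meaningful ordering claim; day length is
computed from standard solar-declination geometry (valid |lat| < 66°).

### Growth and yield

* PAR = 0.5 × global radiation; interception = 1 − exp(−KCAN·LAI) with
  KCAN = 0.85; radiation-use efficiency RUE = 4.2 g MJ⁻¹ intercepted PAR.
* LAI rises linearly in thermal time to a maximum of 4.2 × density/53 333
  at anthesis and senesces linearly to 15 % of the maximum at maturity.
* Daily biomass = RUE × PARint × min(temperature factor, water factor).
  This makes the energy bound `biomass ≤ RUE × Σ PARint` an identity,
  tested as such.
* The temperature factors (PRFTC for photosynthesis, RGFIL for grain fill)
  are piecewise-linear breakpoint tables shipped as data
  (`data/species_default.yaml`), so high-temperature response can be edited
  without touching code.
* Kernels m⁻² = G2 × plants m⁻² × mean of min(water, temperature) factors
  over anthesis ± 7 days. No per-cultivar drought-tolerance parameter is
  encoded: tolerance differences enter only through this shared stress
  window, because the root-based mechanism that field calibrations adjust
  is not identifiable from published coefficients.
* Grain = kernels × Σ G3·RGFIL(T)·(0.3 + 0.7·water factor) mg, capped at a
  harvest index of 0.55 of total biomass (field-standard maximum for
  maize). Yields convert internally from g m⁻² to Mg ha⁻¹.

Nitrogen, phosphorus and potassium are not simulated (the target trials
are managed at optimum nutrient status), and there are no lodging, pest or
post-maturity loss processes. Simulated yields are therefore *potential*
(water/temperature-limited) yields; they run well above typical field
records, and every claim made about them is an ordering or variance-share
claim, never an absolute-yield claim.

### Soil water

Three-layer bucket with volumetric LL < DUL < SAT per layer. Daily order:
curve-number runoff, top-down infiltration (saturation excess returned to
runoff), drainage of 40 %/day of water above DUL cascading downwards,
two-stage soil evaporation from the top layer (energy-limited
`ET0·(1−cover)`, supply-limited at 50 % of evaporable water), root uptake
capped at 10 %/day of plant-available water. The crop water-stress factor
is min(1, extractable supply / transpiration demand). Reference ET uses
the DSSAT Priestley–Taylor equilibrium-evaporation form. Every step
returns a closed budget; season-level closure is asserted below 0.1 mm
(machine precision in practice). The Suleiman–Ritchie evaporation staging
of full DSSAT is deliberately replaced by the simpler two-stage rule.

Auto-planting follows the "plant when moisture is optimal" rule: the first
window day whose end-of-day top-layer plant-available water fraction
reaches 0.4, after a bare-soil spin-up from 25 % PAW. Irrigated
management refills the profile to DUL whenever root-zone PAW drops below a
threshold (0.6 in the pipeline's dry-season environments); amounts are
whatever refill requires, since published protocols state the rule but not
the doses.

## Synthetic weather

Rainfall occurrence is a first-order two-state chain whose wet-day
probabilities follow a Gaussian profile over day-of-year (peak at
mid-season; spread = season length/4), with a +0.35 wet-after-wet
persistence and a 0.95 cap; intensities are exponential with mean
annual_total/(0.45 × season length). The occurrence amplitude is
calibrated once, deterministically, by bisection on the chain's exact
forward marginals so the *expected* annual total equals the archetype
target — the realised 26-year mean then sits within sampling error
(interannual SD ≈ 175 mm for the dry archetype). Archetypes: dry savanna
825 mm, season start DOY 152, 105 days (this concentrates > 50 % of annual
rain in July–August, as in the target climatology); wet savanna 1125 mm,
DOY 121, 150 days. Temperature and radiation are annual sinusoids (warmest
around April) plus bounded uniform noise, with wet-day cooling/cloud
terms; the bounds guarantee Tmax > Tmin on every day. Not represented:
humidity and wind, spatial correlation between sites, multi-day storm
clustering beyond first-order persistence, and any fit to specific station
records — so passing weather tests demonstrates regime-level realism
(totals, seasonality, concentration), not day-level realism.

## Synthetic trials

Y_ijr = μ + G_i + E_j + GE_ij + R_r + ε_ijr. Main effects and the
interaction are drawn, centred and scaled *exactly* to the sums of squares
implied by the requested variance fractions; only the i.i.d. error is left
random, so realised ANOVA shares converge to the targets as the error
fraction → 0 (tested to machine precision at zero error). Interaction
structures: `multiplicative` (sum of `gei_rank` centred outer products
with 1/k weights), `slope` (GE_ij = (β_i − 1)E_j exactly; the GEI share is
then implied by the βs), `unstructured` (full rank). The replicate effect
is a crossed block (one draw per rep, shared by all cells), matching the
ANOVA layout with rep df = r − 1. Defaults are the study conditions: 16
genotypes × 8 environments × 2 reps, grand mean 3.7 Mg ha⁻¹, shares
E/G/GEI/rep/error = 0.67/0.19/0.13/0/0.01, total variance 1.5 (Mg ha⁻¹)².
Environment effects are fixed across reps. What the generator does *not*
emulate: heteroscedasticity across environments, genotype-specific error
variances, and missing cells — all estimators here require balance and
reject incomplete tables rather than imputing.

All generator randomness flows from a single seed through
`numpy.random.SeedSequence`; the documented package default is 20160316.

## Evaluation statistics

Willmott's d uses deviations from the observed mean in the denominator
(the 1981 convention; the primed notation in crop-model papers is
ambiguous but the "1:1 prediction" interpretation fixes it): d ∈ [0, 1].
Nash–Sutcliffe ME ∈ (−∞, 1]; RMSE in data units; bias = mean(simulated −
observed), positive meaning over-prediction (the signed definition is
forced by published tables containing negative entries). Degenerate
denominators raise explicit errors rather than returning NaN.

## Stability battery

All estimators operate on genotype × environment cell means (reps averaged
first); the full-ANOVA error MS feeds the Kang significance tests.

* ANOVA: balanced decomposition; "% variance" is the share of total SS
  (verified against the published table arithmetic), not a REML component.
* Finlay–Wilkinson: slope on the environment index I_j = ȳ.j − ȳ..;
  mean slope is exactly 1 on balanced data; S²d = residual SS/(q−2).
* Ecovalence: double-centred squared interaction, ΣW_i = interaction SS of
  the cell-mean table (asserted to 1e-9 relative).
* Shukla: the standard unbiased estimator
  σ²ᵢ = pWᵢ/((p−2)(q−1)) − ΣW/((p−1)(p−2)(q−1)); affine and increasing in
  Wᵢ, so ecovalence and Shukla ranks coincide; negative values are
  legitimate and never clamped. Published stability tables in this
  literature sometimes label this quantity "SIGMA" while printing a
  different, unreproducible column under the name "Shukla"; this package
  implements the standard estimator and reports it as `sigma2`.
* AMMI: SVD of the double-centred cell means; Σλ² equals the interaction
  SS; scores use the symmetric √λ scaling; zero axes are dropped for
  degenerate (additive) tables. ASV follows Purchase:
  √((SS₁/SS₂·IPCA1)² + IPCA2²), falling back to |IPCA1| with a warning
  when the second axis is empty.
* Kang YSᵢ: yield ranks (1 = lowest) adjusted ±1/2/3 by a t-test of each
  genotype mean against the grand mean, minus a 0/−2/−4/−8 penalty when
  σ²ᵢ is significant at 5/1/0.1 % by an F-test against the pooled error of
  cell means (error MS/r, df = q−1 vs error df). The adjustment and
  penalty lookups are module-level data tables so variants can be swapped.
  Stable = YSᵢ above the mean YSᵢ.
* AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) on the n = p·q cell means.
  Parameter counts (the literature is silent, so they are fixed here):
  additive k = p+q−1; Finlay–Wilkinson adds p−1 slopes; AMMI-m adds
  m(p+q−1−m). A zero-RSS model raises an explicit perfect-fit error
  instead of returning −∞.
* Rank concordance: Spearman ρ per statistic (ties mid-ranked; |bᵢ−1| is
  the ranking key for slopes) plus top-3 overlap.

## Pipeline

The default network is 4 sites × {dry-irrigated, rainy-rainfed} seasons,
with the two soil-profile pits per site (the second pit holds 8 % less
available water) serving as the two simulated replications. Sites differ
by climate archetype, soil, a temperature offset (+3.5 °C hot site,
−1.5 °C highland site) and a rainfall scale — the contrasts a real savanna
network exhibits — which makes the environment main effect dominant in the
simulated ANOVA as it is in real METs. The "observed" arm is a synthetic
surrogate from the trial generator (field records are not published), so
pipeline-level claims are variance-share orderings, rankings and
concordances, never value reproduction. Everything derives from one seed;
two runs with the same config produce byte-identical manifests.

## Numerical choices and degenerate inputs

Ties in ranks get average ranks. Zero-variance trials, constant observed
series, flat environment indices, missing cells, polar latitudes,
inverted Tmax/Tmin, negative rain and weather series ending before
maturity all raise typed, descriptive errors rather than propagating NaN.
Seasonal analysis skips (with a logged warning) years in which the
moisture rule never triggers or the season cannot finish, and errors only
if a cultivar completes no year at all.

## Problem sizes

Defaults used by the tests and the acceptance script: 16 × 8 × 2 trials;
200 generator replicates for share recovery; 100 random tables for oracle
equivalence; 26 + 1 years of daily weather per archetype for the seasonal
analysis; 2-year weather slices per trial environment. These sizes were
chosen as the smallest at which the stochastic claims are comfortably
resolved.

## Known limitations

* The simulator is uncalibrated against any field data set; absolute
  yields are potential yields and high.
* No nutrient, pest, lodging or post-maturity loss processes; no
  per-cultivar drought-tolerance mechanism.
* Balanced designs only; no missing-cell imputation, no REML variance
  components, no GGE biplots, no nonparametric statistics beyond Kang.
* Weather generator is single-site (no cross-site correlation) and omits
  humidity/wind, so Priestley–Taylor is the only sensible ET option.
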
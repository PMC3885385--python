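# Methods

## Indices

The community temperature index (CTI) of a square–survey assemblage is the
unweighted arithmetic mean of the species temperature indices (STI) of the
recorded species; the community temperature variation (CTV) is their
standard deviation. Both are occurrence-based: occurrences are
deduplicated to presence/absence before computation, so abundance never
enters and common and rare species weigh equally. CTV uses the sample SD
(n−1 divisor); the population-SD alternative changes nothing qualitative
and the choice is isolated in `compute_ctv`. A community of one species
has a CTI but no CTV; such squares stay in CTI analyses and drop out of
CTV analyses only. A species occurring in the data without an STI entry is
a hard error — silently dropping it would bias the CTI of every community
containing it.

Wandering species can be excluded a priori (`apply_exclusions`); the
canonical butterfly exclusion list is shipped as a constant.

## Standardization to metres

The group constant *b* is the OLS slope of first-survey index values on
square altitude, fit once per group and never refit inside the bootstrap
(a sensitivity switch allows refitting). Dividing a temporal change by *b*
gives the displacement, in metres along the gradient, at which the same
index difference occurs spatially; the package reports both that signed
quotient (negative = downhill) and its negation, so that positive numbers
mean an uphill community shift — the convention under which a warming
community (ΔCTI > 0, *b* < 0) is a positive shift. If a fitted *b* is ≥ 0
the metres interpretation inverts, so standardization aborts with a
diagnostic unless explicitly overridden.

## Shift–altitude GLS

Standardized shifts are modelled as Gaussian with mean
β₀ + β₁a* + β₂a*² + β₃a*³ + β₄·range, where a* = altitude − 500 m (the
intercept is then the prediction at 500 m) and the within-square
altitudinal range enters raw and uncentred; predictions hold it at its
sample mean. Residual SD is σ·g(r) with r the square's species richness
(mean of the two surveys, switchable to survey 1) and g one of 1 (fixed),
rᵟ (power), or c + rᵟ (constant-plus-power) — indices averaged over richer
communities are more precise, so δ is typically negative on real-like data.

Fitting profiles β (weighted least squares) and σ analytically and
optimizes the remaining variance parameters numerically (bounded scalar
search for δ; Nelder–Mead over (δ, log c) with three fixed jittered
restarts for the constant-plus-power form). Model building follows the
standard protocol for extended linear models:

1. variance structure chosen by REML AIC with the full fixed model held
   constant (both ML and REML likelihoods are stored on every fit);
2. fixed effects backward-selected by ML AIC, removing only the
   highest-order altitude term at a time (hierarchy: cubic before
   quadratic before linear; the intercept never leaves), AIC differences
   below 10⁻⁶ counting as ties resolved toward the simpler model;
3. final refit by REML; nested variance structures tested by REML
   likelihood-ratio tests against χ²;
4. prediction inference by nonparametric case bootstrap: squares resampled
   with replacement, the already-selected model refit per resample (no
   re-selection), 95% percentile intervals, and the two-sided p-value
   2·min(#{pred ≤ 0}+1, #{pred ≥ 0}+1)/(B+1). Resamples whose refit fails
   are redrawn with the count logged; >10% failures aborts. A
   residual-bootstrap variant was considered and rejected as more
   model-dependent; case resampling makes the fewest assumptions about the
   variance function's correctness.

AIC counts every estimated parameter (β, σ, variance parameters). The
REML log-likelihood is defined as the exact Gaussian density of an
orthonormal basis of error contrasts; this includes a −½log|XᵀX| term that
some implementations drop as a constant, so absolute REML values may
differ from other software by a fixed offset while every likelihood ratio
and AIC comparison is unaffected. An influence utility refits the
selected model excluding extreme shift values to confirm the altitude
effects are not outlier-driven (low-richness squares produce the extreme
shifts, and the power variance already downweights them).

Known behaviour of the selection step: on truly homoscedastic data, AIC
accepts a spurious power parameter with probability ≈ P(χ²₁ > 2) ≈ 0.16
and a spurious constant-plus-power pair with ≈ P(χ²₂ > 4) ≈ 0.14, so the
three-way selection recovers the fixed structure in only ~75–80% of null
datasets. This is a property of AIC, not of the implementation, and the
tests assert the attainable rate.

## Temperature-trend LMM

Monthly station series aggregate to the summer half-year mean (Apr–Sep;
a station-year missing any summer month is dropped with a warning) and the
coldest-month mean (minimum of the year's monthly means). Each measure is
modelled as intercept + altitude + trend·(year − first year) +
trend × altitude with crossed random intercepts for station and year.
Because the station networks of interest are tiny (tens of stations), the
model is fit by direct REML maximization on the dense n × n covariance
matrix rather than by sparse mixed-model machinery: variance ratios
γ = σ²ᵤ/σ²ₑ are optimized under non-negativity bounds (L-BFGS-B, three
starts), with β and σ²ₑ profiled. A ratio driven to the boundary is pinned
at 0 with a note. With a single year of data, the year variance *and* the
trend fixed effects are unidentifiable; both are removed, with a note.
Fixed-effect p-values use a t reference with n − p degrees of freedom and
are approximate (no Satterthwaite/Kenward-Roger correction).

## Synthetic data

The generator emulates the design the analysis assumes: ~214 regularly
spaced 1-km² squares spanning 263–2840 m, surveyed twice five years apart
on a rotating five-year panel starting in 2003; richness declining with
altitude; first-survey CTI declining linearly in altitude at roughly
−9×10⁻⁴ index units per metre (the magnitude seen in occurrence-based
monitoring data); and a 14-station temperature network (273–2501 m,
1995–2010) warming at 0.07 °C/yr with a −0.0055 °C/m lapse rate and
station/year random effects.

Species occupancy follows a Gaussian response along altitude
(max_occupancy·exp(−(a − optimum)²/2w²)). STIs are drawn uniformly on the
group's scale (Ellenberg-like 1–5 for plants, °C-like 8–13 for fauna,
optionally snapped to 0.5 steps) and mapped linearly and strictly
decreasingly onto niche optima. Default geometry: optima span (−1200,
4300) m — extending well past the surveyed gradient so edge truncation
does not curve the CTI profile — and niche widths taper from 450 m at low
optima to 300 m at high optima, which gives high-altitude communities a
narrower STI spread and hence the observed negative CTV–altitude slope.
Pool sizes default to the realistic regional faunas/floras (~200 butterfly-
or bird-like species, ~800 plant-like): small pools make the expected CTI
profile ragged, which reads as attenuation when a global *b* is applied
locally. These choices were made once, to realize the stated design
conditions (linear CTI decline at the printed slope magnitudes), and are
exposed as parameters.

A between-survey shift is imposed by raising every species' effective
optimum by s(a) = shift_at_reference + shift_gradient·(a − 500), so the
survey-2 community at altitude a is, in expectation, the survey-1
community at a − s(a); the expected standardized shift therefore equals
s(a) wherever the CTI profile is locally linear. Occupancy rows are
rescaled by a common square-specific factor so expected survey-1 richness
matches richness_at_reference·exp(−richness_decay·(a − 500)); the factor
is shared between surveys and across species, preserving relative
composition and hence the CTI. Detection noise thins occurrences
uniformly (false negatives only), which perturbs richness but not the
CTI's expectation. Presences are drawn independently across squares and
surveys — no within-square temporal persistence, no spatial
autocorrelation, no abundances, no land-use change. Consequences: the
paired-difference analysis the pipeline performs is exercised exactly, and
nulls are exact, but passing tests say nothing about robustness to
temporal autocorrelation of detection, observer effects, or spatially
structured drivers in real monitoring data.

## Problem sizes used in the checks

The calibration tests run the full pipeline at the study design size
(214 squares): 100 replicate campaigns with B = 500 bootstrap iterations
for recovery/coverage of an imposed +40 m shift, and 200 replicates with
B = 199 for the null false-positive rate — sizes chosen to make binomial
tolerances meaningful while keeping the default suite fast. Likelihood
oracles run on deliberately tiny instances (6 observations; 3 stations ×
4 years) where brute-force density evaluation is exact.

## Limitations

* The percentile bootstrap under model selection is slightly liberal; the
  coverage test documents ~93–95% realized coverage at nominal 95%.
* REML AICs are compared across variance structures with fixed effects held
  identical; they are never compared across different fixed effects.
* The LMM's t-based p-values use residual df; for very small station
  networks they are approximate.
* Standardization presumes a negative, roughly linear index–altitude
  relation; the CTV–altitude slope can legitimately be ~0 on synthetic
  data, in which case the CTV branch aborts (or is skipped by the
  pipeline with a logged reason) rather than producing sign-flipped
  output.
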
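# thermocomm

Thermophilization analysis for repeated biodiversity surveys along
elevation gradients: are local species communities shifting towards
warm-dwelling species, and does the rate of that shift depend on altitude?

The package is aimed at analysts of monitoring-scheme data (repeated
presence/absence surveys of plants, butterflies, birds, … on fixed sample
squares) who want a tested, reproducible implementation of the community
temperature index framework, including its conversion to metres of
equivalent altitudinal displacement and the heteroscedastic regression and
bootstrap machinery around it. A synthetic-data module emulates the
two-survey monitoring design end to end, so every stage can be exercised —
and its statistical calibration checked — without access to any field data.

## The statistics

For a community at sample square *i*, with STI(s) the temperature-niche
position of species *s* (a long-term mean temperature, or an Ellenberg-like
indicator value for plants):

* **CTI** (community temperature index) = mean of member STIs, unweighted,
  occurrence-based; **CTV** (community temperature variation) = SD of
  member STIs.
* **Standardization**: with *b* the slope of the group's first-survey
  CTI–altitude regression, the temporal change ΔCTIᵢ between two surveys
  converts to a displacement ΔCTIᵢ/*b* in metres along the gradient.
  Example: ΔCTI = 0.05 with *b* = −0.001 gives 0.05/−0.001 = −50 m — the new
  community is the one found 50 m downhill, i.e. the community shifted
  50 m *uphill*. The package reports both the signed quotient and the
  uphill-positive shift.
* **Shift–altitude model**: standardized shifts are modelled by GLS on
  linear/quadratic/cubic altitude (centred at 500 m) plus the within-square
  altitudinal range, with residual SD σ·g(richness) where g is 1, richnessᵟ
  or c + richnessᵟ. The variance structure is chosen by REML AIC, fixed
  effects by backward ML-AIC selection, terms tested by REML likelihood
  ratios, and predictions at 500 m and 2350 m get percentile CIs and
  p-values from a nonparametric case bootstrap over squares.
* **Temperature trend**: summer (Apr–Sep) and coldest-month station means
  are modelled with a crossed random-intercept LMM (station, year) testing
  the trend × altitude interaction.

## Worked example

```python
import thermocomm as tc

pool = tc.generate_species_pool(200, sti_bounds=(8.0, 13.0), seed=1)
scenario = tc.ShiftScenario(shift_at_reference=40.0,           # +40 m uphill at 500 m
                            shift_gradient=-40.0 / 1850.0,     # fading to 0 at 2350 m
                            richness_at_reference=33.0, seed=2)
dataset = tc.generate_surveys(pool, scenario)
table = tc.index_table(dataset, tc.StiTable(pool.sti_table("butterflies")),
                       "butterflies")
changes, slope = tc.standardized_changes(table, kind="cti")
X, y, richness = tc.build_design(changes, tc.ModelSpec())
kind, _ = tc.select_variance_structure(X, y, richness)
spec, fit, _ = tc.backward_select(changes, variance=kind)
boot = tc.bootstrap_predictions(changes, spec, targets=(500.0, 2350.0),
                                B=1000, seed=3)
print(f"b = {slope.b:.3e}")
print(boot.summary_frame().round(2))
```

prints

```
b = -9.373e-04
   altitude_m  prediction_m  ci_low  ci_high     p
0       500.0         44.20   27.20    61.71  0.00
1      2350.0          9.32  -15.03    31.66  0.48
```

The first-survey CTI declines by ≈9×10⁻⁴ index units per metre of
altitude. The selected model predicts a +44 m uphill community shift at
500 m (bootstrap CI excluding zero: the imposed +40 m shift is detected),
while at the 2350 m tree line — where the imposed shift is zero — the CI
comfortably covers zero. The scripts in `examples/` walk through each
stage (simulation, indices and standardization, the GLS model, the
temperature LMM, and the full multi-group pipeline) and print the numbers
above with commentary.

A thin CLI mirrors the library for shell use:

```sh
thermocomm simulate --group butterflies --out data/ --seed 1
thermocomm indices --occurrences data/occurrences.csv --squares data/squares.csv \
    --sti data/sti.csv --group butterflies --out indices.csv
thermocomm standardize --indices indices.csv --out changes.csv
thermocomm model --changes changes.csv --targets 500,2350 --nboot 1000 \
    --seed 42 --out fit.json
thermocomm all --out run/ --seed 1
```

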
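# stormexcess

Bayesian ensemble estimation of short-term excess mortality after tropical
cyclones, for epidemiologists and climate-health researchers working with
county-month death panels.

After a tropical cyclone, deaths rise for reasons that death certificates
rarely attribute to the storm. The standard measure is **excess deaths**:
observed deaths minus the counterfactual deaths expected had the storm not
occurred, over the month of exposure and the month after. `stormexcess`
implements that design end to end:

1. **Exposure classification** — daily county peak sustained winds are
   classified on the Beaufort scale (gale to violent storm force:
   34–63 knots; hurricane force: ≥ 64 knots) and rolled up to county-month
   exposure categories with month-of/month-after target windows.
2. **Counterfactual modelling** — an ensemble of 16 Bayesian count models
   (2 trend options × 4 autoregressive orders × 2 temperature options) is
   fitted per county on cyclone-free periods:

   ```
   deaths_t ~ Poisson(exp(η_t))
   η_t = α₀ + θ_month + ζ_t + (β + ω_month)·t + (γ + ν_month)·anomaly_t
         + log(population_t) + ε_t
   ```

   with seasonal month effects θ (and slopes ω), a stationary AR latent
   series ζ of order 1/2/4/6, an overall temperature-anomaly slope γ with
   circular random-walk month modifiers ν, a log-population offset, and
   i.i.d. overdispersion ε. Fitting uses an empirical-Bayes Laplace
   approximation (see `docs/methods.md`).
3. **Validation and weighting** — cyclone-free two-month windows are
   withheld; each model's mean percentage error determines its share of
   posterior draws (proportional to 1/|MPE|, capped at 1000, floored at 0).
4. **Excess summaries** — pooled counterfactual draws give excess-death
   point estimates, 95% credible intervals (2.5th/97.5th percentiles) and
   posterior probabilities of excess > 0, aggregated by county-year,
   state-year, storm, wind category, or social-vulnerability tertile, with
   probability-filtered totals and tertile-vs-tertile comparisons.

Restricted real mortality data are not required: a first-class synthetic
panel generator produces county-month panels with known injected excess, so
the whole pipeline is testable against ground truth.

## Worked example

```python
import stormexcess as se
from stormexcess.countmodel import FitConfig, enumerate_specs

# a 10-county, 10-year panel with a 25% mortality increase in the month
# of and month after each simulated storm
cfg = se.SimConfig(n_counties=10, n_years=10, storm_rate=0.5, seed=3)
panel, calendar, truth = se.generate_panel(cfg)

specs = [s for s in enumerate_specs() if s.model_id in (2, 3, 8, 13)]
ens = se.ExcessDeathEnsemble(panel, calendar, specs=specs,
                             fit_config=FitConfig(n_draws=500),
                             svi=se.generate_svi_table(10, 3))
res = ens.fit(seed=3)
print(res.summary())
```

```
Tropical-cyclone excess mortality ensemble
================================================
members: 4   pooled draws: 1367
target county-months: 76   counties: 10
total excess deaths: 909.2 [95% CrI 779.0, 1039.5]  P(excess>0) = 1.000
model  mean % error  draws
    2       -0.339    306
    3       -0.207    500
    8       -0.585    177
   13       -0.270    384
ensemble mean % error: -0.303
```

The validation table shows each member's signed mean percentage error on
the withheld windows and the draw allocation it earned (the best model is
anchored at the cap — here the 500 configured posterior draws). The pooled
estimate of 909 excess deaths [779, 1040] brackets the injected ground
truth of 825 expected excess deaths. Grouped summaries come from the same
results object:

```python
res.by(["category"], probability_filter=0.95)
```

```
             category  point_estimate  cri_low  cri_high  posterior_probability  n_members
gale_to_violent_storm           788.2    681.2     900.7                  1.000         18
            hurricane            17.5      0.2      34.0                  0.974          1
```

i.e. restricting to county-years whose own posterior probability of excess
exceeds 95%, 788 excess deaths followed gale-to-violent-storm-force winds
(18 qualifying county-year units) and 18 followed hurricane-force winds.

The same pipeline runs from the shell on CSV inputs:

```bash
stormexcess simulate --seed 7 --n-counties 10 --out simdata
stormexcess classify --wind simdata/wind.csv --out out
stormexcess run --config pipeline.yaml
stormexcess sensitivity --config pipeline.yaml   # window / split-period checks
```

## Layout

| module | role |
| --- | --- |
| `stormexcess.exposure` | wind classification, exposure calendar, tallies |
| `stormexcess.preprocess` | June-anchored population interpolation, temperature anomalies, panel assembly |
| `stormexcess.countmodel` | the 16 model specs and the Laplace-fitted county count model |
| `stormexcess.validation` | withheld-window validation, inverse-error weighting, draw pooling |
| `stormexcess.aggregation` | excess draws, summaries, grouped/filtered aggregation, tertiles |
| `stormexcess.ensemble` | `ExcessDeathEnsemble` / `ExcessDeathResults` orchestration, sensitivity harnesses |
| `stormexcess.simulate` | synthetic panels, storms, SVI tables with ground truth |
| `stormexcess.io`, `stormexcess.pipeline`, `stormexcess.cli` | CSV schemas, YAML-driven pipeline, command-line interface |

`docs/methods.md` documents the model, priors, numerical choices and
limitations in detail.
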
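# Methods

`stormexcess` estimates short-term excess all-cause mortality after
tropical cyclones from county-month death panels. This note records the
model, the numerical choices behind the implementation, what the synthetic
data generator does and does not emulate, and the package's known limits.

## Study design

Excess deaths in a county are defined as observed deaths minus the
counterfactual deaths that would have occurred had the storm not passed,
over the month of exposure and the following calendar month. The
counterfactual is not observable; it is predicted by count models trained
only on cyclone-free periods of the same county's history.

Exposure is classified from daily county peak sustained wind: a county-day
with wind ≥ 34 knots is tropical-cyclone exposed (gale to violent storm
force when 34 ≤ wind < 64 knots, hurricane force when wind ≥ 64 knots). A
county-month takes the maximum severity over its days. Both thresholds are
configurable but default to the Beaufort-scale values above.

When the month after storm A is also the month of storm B, the month is a
target once and its excess is split equally between the contributing storms
for storm-level totals, each storm keeping its own wind category. This is a
declared convention of the package: no unambiguous attribution rule exists
for overlapping storm windows, and the equal split conserves totals by
construction.

## The count models

For one county, monthly deaths follow

    deaths_t ~ Poisson(exp(eta_t))
    eta_t = alpha0 + theta_{m(t)} + zeta_t + (beta + omega_{m(t)}) * t
            + (gamma + nu_{m(t)}) * a_t + log(P_t) + eps_t

with month-of-year m(t), temperature anomaly a_t (deviation of the month's
temperature from that county's long-run mean for the same calendar month),
and interpolated monthly population P_t as an offset. The components:

* `alpha0`, `beta`, `gamma` — fixed effects with N(0, 1000) priors
  (variance 1000). The time covariate is scaled by 1/120 internally for
  conditioning; slopes are reported per month.
* `theta` — seasonal month intercepts. The generative prior is the
  intrinsic period-12 seasonal structure (every sum of 12 consecutive terms
  is an independent zero-mean Gaussian). For a stationary 12-vector that
  structure penalises only the annual total, so the fitted model uses 12
  month effects under a hard sum-to-zero constraint with an exchangeable
  N(0, sigma_theta^2) prior on that subspace; the level is absorbed by
  `alpha0`. The generative window-sum recursion is implemented separately
  (`priors.sample_seasonal_path`) and verified by a prior-predictive test.
* `omega` — seasonal slopes, paired with `beta` as the `(beta + omega)*t`
  block and present exactly when the trend is on; same structure as
  `theta`.
* `nu` — month-specific temperature slopes with a circular first-order
  random-walk prior over the 12 months (December adjacent to January),
  sum-to-zero constrained.
* `zeta` — a stationary autoregressive series of order 1, 2, 4 or 6,
  parameterised by partial autocorrelations r_j in (−1, 1), each given an
  N(0, 1) prior on log[(1+r)/(1−r)], with a Gamma(0.001, 0.001) prior on
  the marginal precision exp(kappa1). For order 1 this reduces exactly to
  the standard (kappa1, kappa2) parameterisation, with
  kappa1 = log[(1−phi²)/sigma²] the log marginal precision. Higher orders
  generalise the order-1 specification through the same transform applied
  to every partial autocorrelation; this is a design choice where only the
  order-1 hyperpriors are standard.
* `eps` — i.i.d. overdispersion on the log scale, Gamma(0.001, 0.001) on
  its precision.

Precision hyperpriors are specified as log-Gamma on each log precision,
i.e. Gamma(0.001, 0.001) on the precision itself.

The ensemble is the full 2 × 4 × 2 grid — trend block on/off, AR order in
{1, 2, 4, 6}, temperature block on/off — giving 16 models, enumerated
trend-major, then AR order, then temperature.

## Posterior computation

Fitting uses an empirical-Bayes Laplace approximation, the same
approximation family used by latent-Gaussian frameworks for models of this
form:

1. For a candidate hyperparameter vector, the mode of the latent Gaussian
   field is found by Newton iterations with backtracking (the Poisson
   log-likelihood runs over training months only; latent states at target
   months carry no data term and are propagated through their priors).
2. The Laplace approximation of the marginal posterior of the
   hyperparameters (log-likelihood at the mode + prior + half log-dets) is
   maximised with L-BFGS-B over the transformed hyperparameters, with
   bounds of ±16 on log precisions and ±5 on pacf transforms to keep the AR
   comfortably stationary.
3. At the optimum, posterior draws come from the Gaussian approximation at
   the joint mode; hyperparameters are fixed at their modal values.

Internally the AR series and the overdispersion terms are carried as one
residual component u_t with covariance Sigma_AR + sigma_eps² on training
months — an exact reformulation that halves the latent dimension. At
held-out months u_t is the propagated AR state alone, and predictions add a
freshly drawn overdispersion term, so the posterior-predictive count for a
target month is Poisson(exp(eta_draw + fresh eps)). Re-drawing eps for
counterfactual months (rather than carrying over a training-month value) is
a deliberate choice: the overdispersion term is i.i.d., and a counterfactual
month is a new realisation.

Fixing hyperparameters at their mode ignores hyperparameter uncertainty.
The parameter-recovery study in the acceptance suite shows the resulting
credible intervals for the temperature slope hold close to nominal
coverage at the panel sizes used here; posterior uncertainty for weakly
identified variance components (sigma_zeta vs sigma_eps) is understated,
which matters little for counterfactual prediction since only their sum
enters the predictive variance.

A fit is flagged non-convergent when the optimiser or the mode are
non-finite; a model with any non-convergent fit receives zero ensemble
draws. The degenerate configuration `random_effects=False` drops every
random component and reproduces the closed-form intercept-only Poisson
regression, which the tests verify against the analytic MLE and an
independent GLM fit.

## Validation and ensemble weighting

Two-month cyclone-free windows (default: March–April of the first and last
clean years of the panel) are withheld; every model is refit without them
and predicts the window totals pooled over counties. The signed percentage
error is 100 × (predicted − observed)/observed, and the mean percentage
error (MPE) averages the windows. Because validation error is a pooled,
panel-level property, the pooled county set may be a configured subset.

Draw allocation is proportional to 1/|MPE| with the best model anchored at
the draw cap (1000 by default; scaled runs use the configured posterior
sample size as the cap) and a floor of zero. A model with MPE exactly 0
takes the cap and others scale against the next-best finite value. The
anchor-at-cap normalisation is the package's choice; only the cap and floor
are externally fixed. Pooling concatenates each model's first `weight`
draws after a per-model seeded permutation of whole joint draws, so
cross-month dependence within a model is preserved.

## Excess aggregation

Excess draws are observed deaths minus pooled counterfactual draws per
target county-month. Counties are fitted independently, so their draw
vectors are paired independently: each county-month's draws are permuted by
a deterministic function of its own key and the seed before any group sum.
Because the permutation does not depend on the grouping, county → state →
national sums are conserved exactly per draw index (draws are
integer-valued, so float sums are exact).

Summaries report the posterior mean (the package's choice of point
estimate, recorded in output metadata), the 2.5th/97.5th percentile
credible interval, and the posterior probability of excess > 0.
Probability-filtered totals (default threshold 0.95) include only member
units — county-years, optionally refined by storm or wind category — whose
own posterior probability exceeds the threshold, and re-summarise the
pooled draws of the passing members rather than summing member intervals.
Group-vs-group probabilities count strict inequalities, with ties reported
separately and counted as 1/2 in the tie-adjusted value.

Social-vulnerability tertiles are assigned either by within-sample rank
thirds (ties broken by county id) or by cutting the percentile scale at 1/3
and 2/3 — the latter can give unequal tertile sizes in a subsample of
counties, as observed in real analyses. Both modes are provided, nationally
or within state, for the overall index or any of its four components; the
mode used is recorded in the output.

## Synthetic data

The generator produces county-month panels from the same structure the
models assume: log death rate = baseline + seasonal month effect + linear
trend + stationary AR noise (simulated through the same
partial-autocorrelation parameterisation the fitter uses, so simulator and
fitter cannot disagree) + (overall + month-specific) temperature-anomaly
effect + i.i.d. overdispersion, with deaths drawn Poisson. Populations are
generated annually and interpolated with the same June-anchored routine the
pipeline applies to real inputs. Storm calendars are built by running the
wind classifier on simulated daily peak winds (34 + Exponential(10) knots,
putting ~5% of storm-months at hurricane force), with storms confined to
May–November and a September mode. Excess mortality is injected
multiplicatively in the month of and month after each exposure.

Default conditions: 40 counties × 16 years; baseline 7.5 × 10⁻⁴ deaths per
person-month (~9 per 1000 per year); ±8% winter/summer seasonal swing; a
−0.02%/month trend; AR(1) with partial autocorrelation 0.5 and innovation
sd 0.02; temperature effect 0.5% per degree anomaly with a ±0.3% seasonal
modifier; overdispersion sd 0.02; 0.3 storms per county-year; and a 25%
mortality increase in both target months. The increase is a free parameter
of the generator, not an estimate of real post-storm mortality.

Not emulated: spatial correlation between counties, storm tracks spanning
counties, precipitation, cause-specific mortality, and demographic
structure. Passing tests therefore demonstrate that the estimator recovers
known effects when its structural assumptions hold, not that those
assumptions hold for any particular real panel.

## Problem sizes and numerical choices

The test and acceptance studies run at desk scale, chosen as the smallest
sizes at which the checked properties are statistically identifiable:

* Degenerate-oracle and exchangeability checks: 1 county × 10 years.
* Parameter recovery: 50 replicates of 1 county × 16 years with phi = 0.6,
  gamma = 0.01, AR innovation sd 0.05 and populations of 200k–500k — the
  regime where the latent AR signal is identifiable behind Poisson noise
  (monthly deaths in the low hundreds). The AR coefficient check is on the
  across-replicate mean: at these panel sizes individual posterior modes
  scatter by more than ±0.2 in a minority of replicates without indicating
  bias.
* Predictive calibration: 10 counties × 16 years, 20 held-out months each
  (200 county-months).
* Excess recovery: 40 counties × 10 years (~230 target county-months) with
  a 4-member sub-ensemble spanning the grid (AR orders 1, 2, 4, 6; trend
  and temperature each on and off); the full 16-member grid runs the same
  way at proportional cost. Null calibration uses 30 counties × 10 years
  with multiplier 1.

Degenerate inputs and tie-breaks: negative winds, non-rectangular panels,
missing population years, and windows overlapping exposure are rejected
with errors; targets past the panel end are truncated with a warning;
tertile ties break by county id; linear predictors are clipped at ±40 on
the log scale before exponentiation.

## Limitations

* Hyperparameter uncertainty is not propagated (empirical Bayes); interval
  widths for variance components are optimistic.
* Counties are modelled independently; no spatial pooling, so small
  counties have wide counterfactual intervals.
* The validation-window scheme assumes the withheld months are
  representative; windows are configurable precisely because that is an
  assumption.
* The equal-split storm attribution rule is a convention; storm-level
  totals for overlapping storms depend on it.
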
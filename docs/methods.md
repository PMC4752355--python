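# Methods

## Design

The analysis treats the 2009 onset of the economic crisis in Spain as a
natural experiment: exposure (living through the recession) was not
assigned, so causal leverage comes from (a) a comparison group —
individuals who had not consumed any psychotropic drug before January 2009
— constructed with propensity scores ("selection on observables"), and
(b) a random-coefficient panel model absorbing unobserved individual and
temporal heterogeneity ("selection on unobservables", the panel-data
equivalent of difference-in-differences). The estimand is the relative
risk of psychotropic consumption in 2009–2012 versus 2005–2008, overall,
per drug class (benzodiazepine anxiolytics vs SSRI/SNRI antidepressants)
and per subgroup.

## Outcomes

Consumption is measured on consuming person-months only (a panel row exists
when at least one dispensing occurred that month):

* **drug count** `n_drugs`: distinct active substances dispensed in the
  month, a severity proxy (min 1 by construction);
* **DDD** `ddd`: defined daily doses dispensed in the month. Each record
  contributes `n_packs × units_per_pack × amount_per_unit(mg) / DDD_ATC(mg)`;
  records are summed within the calendar month. The quotient is a monthly
  total, not a per-day average: the analysed quantity is the month's
  aggregate, and dividing by month length would only rescale it. DDD
  reference values ship as an editable CSV (WHO ATC oral DDDs, 2014 index
  vintage) and are configuration inputs, not constants.

## Model

For individual `i`, month `t = 1..96`:

    g(E[Y_it]) = η_it = β₀ + x_itᵀβ + b_i + α_t(i) [+ e_it]

* `poisson_count` family: `g = log`, `Y ~ Poisson`. Overdispersion is
  realized as iid Gaussian observation-level effects `e_it ~ N(0, σ_e²)` —
  the standard Bayesian surrogate for a quasi-Poisson dispersion factor φ.
* `gaussian_ddd` family: `g = identity`, constant residual variance σ².
  (A mean-proportional variance is not coherent for a Gaussian outcome;
  the constant-variance reading is adopted.)
* `b_i ~ N(0, σ_b²)`: unobserved individual heterogeneity.
* `α`: random walk of order 1 over months, innovation sd `σ_α`, carried
  with a sum-to-zero constraint per path so the intercept stays identified.
  Default is one shared path; `rw1_mode="by_individual"` gives each
  individual a path (the fuller specification) at a memory/time cost —
  shared-path plus individual intercepts is the desk-scale default.
* Fixed effects and reference categories: sex (ref. men), age group
  (ref. 15–34; re-evaluated monthly from birth date), country of birth
  (9 groups, ref. Spain), metabolic syndrome, cancer (ref. none; levels
  neoplasm / fear of cancer), unemployment-probability quintiles (ref.
  first) for both all and long-term unemployment, monthly physician
  visits, family-in-cohort, and the post-2009 step. All but sex and
  country are time-varying.

The period effect enters as a fixed step indicator at January 2009
(`t = 49`); the published source reports period RRs without showing the
period term in the predictor, so both routes are implemented: the fixed
step (default) and a contrast of the fitted monthly path
(`monthly_rr_path`). A relative risk is the antilog of a posterior
contrast, summarized by its median and central 95% credibility interval;
"significant" means the interval excludes 1. Subgroup RRs use
period-by-subgroup interaction columns in a single refit per stratifier
(stratified refits are the switchable alternative). No multiplicity
adjustment is applied across subgroup rows, mirroring the original
presentation; the global-null calibration test documents the consequence
(~5% of null rows flag).

### Priors

Unstated in the source; weakly-informative defaults, all overridable:
`β ~ N(0, 5²)`, half-Normal(0, 1) on every sd (σ_b, σ_α, σ_e, σ). With
outcomes on the scale of 0–3 drugs or DDDs these priors are flat over the
plausible range.

### Covariate derivations

* **Metabolic syndrome** (NCEP ATP III): ≥3 of {hypertension diagnosis;
  type-II diabetes diagnosis OR fasting glucose in (101, 126] mg/dL; BMI
  > 30; triglycerides ≥ 150; HDL < 40 (men) / < 50 (women)}. Missing
  components count as absent and are logged. The glucose band is
  implemented exactly as specified including its (clinically unusual)
  upper bound; hypercholesterolemia (≥200 mg/dL) is derived and stored but
  is not an MS component.
* **Unemployment probability**: logistic regression of a binary
  unemployment label (and separately, long-term unemployment) on
  conditioning covariates, scored monthly for every individual. The exact
  published specification is not available; the logistic interface is
  pinned and external coefficients can be injected verbatim, so a future
  transcription drops in without code change. Quintiles are pooled
  empirical 20/40/60/80 cut points over person-months, ties to the lower
  quintile.
* **Propensity adjustment**: logistic propensity of pre-crisis consumer
  status; quantile stratification (default 5 strata) entering the outcome
  model as a fixed factor, or 1:1 greedy nearest-neighbour matching with
  replacement within a caliper of 0.2 sd of the logit propensity. The
  matching ratio, caliper and stratum count are unstated in the source;
  these are the conventional defaults and all are configurable.

## Inference

No probabilistic-programming backend is assumed; the samplers are written
for this latent-Gaussian panel structure and vectorized over the panel:

* **Gaussian family** — blocked Gibbs: conjugate draws for β, for the
  individual intercepts, and for the RW1 path (tridiagonal precision,
  banded Cholesky; by-individual paths via a vectorized Thomas
  factorization across individuals); log-scale random-walk MH for the sds.
* **Poisson family** — Metropolis-within-Gibbs, all blocks vectorized:
  the `e` field and the `b` vector have conditionally independent sites
  (per-site likelihood terms reduce to grouped sums maintained by
  `bincount`); the RW1 path updates in an even/odd checkerboard over
  months (the RW1 prior is Markov, so one colour is conditionally
  independent given the other); β moves jointly under a preconditioned
  random walk whose covariance starts at the ML-GLM covariance and is
  refreshed from the warmup history.

Two move families deal with the posterior ridges this model creates:

* **Translation moves** (η-invariant, accepted on the prior ratio alone):
  between the period coefficient and the RW1 path (a step added to β and
  subtracted from post-period path values), and between any
  individual-constant covariate (sex, country, family) and the `b`
  vector. Without these, cluster-level coefficients mix at the rate of
  the random-effect Gibbs scan rather than the data's information.
* **Rescale moves**: joint proposals of an sd and its whole effect vector
  (`e' = e·s'/s`), under which the effect prior cancels against the
  Jacobian — the standard cure for the funnel between a variance and a
  weakly-identified field.

After every update of `b`, `α` or `e` the block is re-centered and its
mean absorbed into the intercept, which leaves η untouched and realizes
the sum-to-zero constraints. Convergence is monitored by split-R̂ per
scalar parameter (via arviz); results refuse to produce relative risks at
max R̂ ≥ 1.1 unless forced. Chains start at the ML-GLM fit; default runs
use one chain with equal warmup and sampling lengths.

### Identifiability of the period step

A step indicator and a free RW1 path are only weakly separable: a random
walk produces period-mean differences cheaply (under the RW1 prior the
sd of the 2009–2012 vs 2005–2008 path-mean contrast is ≈ 5.5 σ_α), so
with σ_α > 0 the realized path drift of any single simulated dataset
enters the step's posterior. This is a property of the model, not of the
sampler — independent long chains agree on the split. Consequences:
(a) parameter-recovery studies here simulate with σ_α = 0, making the
step the sole time signal while the fitted model still carries the RW1
block and must shrink it; (b) on real-format data the monthly RR path is
the more faithful description of when change happened, and the smoothing
inherent in the RW1 prior spreads a sharp step over a few adjacent months
(the step-detection study finds the band excluding 1 from the true onset
month onward, with onset smeared ~3 months earlier).

## Synthetic cohort generator

The generator simulates from the model above with known parameters, under
study conditions: 96 months (Jan 2005–Dec 2012), crisis onset at t = 49,
default 10⁴ individuals; cohort marginals at the published values (66.6%
women, age mean 54.4 sd 17.7 truncated to [15, 95], 92.8% born in Spain
with the published country mix renormalized to sum to one, 1.6% metabolic
syndrome via consistent clinical trajectories, 20.2% with family in the
cohort, 13.2% pre-2009 non-consumers); visits Poisson with mean 2.25 per
month (between the published sex-specific means); unemployment from a
latent logistic in age/origin/frailty with a post-crisis surge, from
which quintile occupancies *emerge* rather than being set (the published
occupancies do not sum to 100% and are not usable as targets). Count
intercept log(0.35) makes the truncated mean among consumers ≈ 1.19
drugs/month, matching the published descriptive level; DDD defaults are
calibrated to the published means/sds, the only moments reported.
Default planted period effects are the published headline magnitudes:
log(1.14) on the count, log(1.077) on the DDD.

Dispensing records are constructed backward from the simulated monthly
totals (substances uniform over the 11 study drugs, Dirichlet DDD split,
one 28-unit pack per substance with the per-unit amount chosen to hit the
target), so `ddd.aggregate_monthly` round-trips the panel exactly. The
drawn count is capped at the 11 available substances. Negative Gaussian
DDD draws are floored at zero. By default the panel keeps consuming
months only (count ≥ 1), as in the source data; `keep_zero_rows=True`
keeps the full untruncated panel, which simulate-then-fit studies use.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: drug-switching and adherence dynamics, serially
correlated clinical trajectories, informative visit processes, household
linkage beyond a binary flag, geographic structure, and any true
event-level dispensing pattern (only monthly aggregates matter
downstream).

## Numerical choices and problem sizes

Quantiles are linear-interpolation percentiles throughout; quintile and
stratum ties break toward the lower bin. Separation in any logistic fit
falls back to an L2-penalized fit with a warning. Duplicate dispensing
records are summed, never deduplicated (logged). The month index maps
t = 1 to January 2005 and accepts `YYYY-MM` strings.

The shipped studies run at desk scale, chosen to make each check sharp
but cheap: recovery and calibration studies use 150–300 individuals × 96
months with 900–1500 post-warmup draws per fit and 20 replicates; the
acceptance script's single-fit demonstrations use 500 × 96. Generator
defaults (10⁴ individuals) reproduce published descriptive levels; model
studies subsample because the sampler's per-iteration cost is linear in
panel rows.

## Known limitations

* The Poisson family is fitted to a count that is ≥ 1 among consumers
  without an explicit truncation term, as in the source; period contrasts
  are unbiased under the design but intercepts absorb the truncation.
* Quasi-Poisson φ is represented by an observation-level effect sd, not
  reported on the φ scale. σ_e is weakly identified at small counts; its
  posterior leans on the half-Normal prior.
* By-individual RW1 paths are supported but summarized through the
  population-mean path; per-individual path uncertainty is not stored.
* The published RR tables print point estimates only (no intervals), so
  only the magnitude and the significance-flag logic are checkable
  against them, not interval widths.
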
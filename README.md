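# mstlife

Multistate disability-transition modelling and health expectancies for
interval-censored elderly panel data.

Longitudinal surveys of older adults (the motivating design is the Chinese
Longitudinal Healthy Longevity Survey, CLHLS: staggered entry at ages 65–95,
interview waves roughly three years apart, family-reported death dates)
observe disability only at wave interviews.  `mstlife` treats a person's
functional status as a continuous-time Markov chain on four states — no
disability (0), mild disability (1), severe disability (2) and death (3) —
graded from the ten BADL/IADL activity items, and provides the full analysis
chain for epidemiologists working with such panels:

- **Intensity model.** Each allowed transition r→s has intensity
  `q_rs(z) = exp(β₀_rs + β_rs·z)` with covariates z = (age − 65, female,
  rural); proportional hazards on every arrow.  Rows of the intensity
  matrix Q sum to zero; `P(t₁,t₂) = ∏ exp(Q(a)·Δa)` by matrix exponentials
  over an age grid.
- **Interval-censored panel likelihood.** Living states contribute
  `log P_rs(a₁,a₂)` between consecutive waves; an exactly dated death at
  age d after a last observation in state r contributes
  `log Σ_j P_rj(a,d)·q_{j,death}(d)` (state at the moment of death unknown);
  censored subjects contribute nothing after last contact.  Maximum
  likelihood by quasi-Newton iteration, observed-information covariance,
  percentile bootstrap (resampling subjects, default B = 499).
- **Multistate life tables.** Health expectancies
  `e_rs = ∫ P_rs(a₀,u) du` by trapezoidal integration (default grid 0.25 y
  to age 115), per initial state and population-averaged with the
  empirical baseline state distribution; TLE/ND/MD/SD/AD plus proportions.
- **Cox onset hazards.** Mild+severe merged into "any disability"; the four
  nested adjustment models (univariate; + age/sex/region;
  + sociodemographics/behaviors; + chronic diseases) with explicit
  missing-value dummy levels; Breslow ties by default (Efron selectable).
- **PMM multiple imputation.** Predictive mean matching for baseline
  covariates, m = 5 imputations, k = 5 donors, results pooled by the plain
  across-imputation mean.
- **Synthetic cohort generator.** Gillespie-style trajectories under a known
  intensity model, wave sampling with dropout, exact deaths and item-level
  covariate missingness — every estimator can be validated against ground
  truth without any restricted survey data.

## Worked example

Simulate the designed calibration cohort (n = 2000, 5 waves at 3-year
spacing), fit the no-jump model, and build a life table with bootstrap CIs:

```python
from mstlife.simulate import calibration_scenario, calibration_true_model, generate
from mstlife.fit import fit_mle
from mstlife.lifetable import life_table, render_life_table

true = calibration_true_model()
subjects, truth = generate(calibration_scenario(n=2000), seed=1)
fit = fit_mle(subjects, true.spec)
table = life_table(fit, subjects, strata=[("male", "urban")],
                   index_ages=[65.0], bootstrap_B=19, seed=1)
print(render_life_table(table))
```

Output (abridged):

```
cohort: 1892 subjects kept, 108 flagged for exclusion
log-likelihood -6704.9, converged=True
  logq_01            -1.941 (SE 0.075)   truth -1.897
  logq_23            -1.250 (SE 0.064)   truth -1.204
  beta_01:female     +0.221 (SE 0.096)   truth +0.250
  beta_23:female     -0.290 (SE 0.087)   truth -0.300
== urban male, index age 65 ==
  start=0: TLE=11.06 (10.55,11.81)  ND=7.35 (6.90,8.08)  ...  PAD=33.6%
  start=1: TLE=8.89 (8.25,9.29)   ...  PAD=60.0%
  start=2: TLE=5.36 (4.83,5.76)   ...  PAD=77.0%
  start=population: TLE=8.09 (7.40,9.14)  PND=46.7%  PAD=53.3%
```

Every estimated log-intensity sits within about one standard error of the
generating truth; total life expectancy falls with worse initial state
(11.1 → 8.9 → 5.4 years), and the share of remaining life spent disabled
rises (33.6% → 60.0% → 77.0%).

A command-line pipeline wraps the same stages:

```bash
mstlife simulate --outdir out --seed 5 --n 2000
mstlife all --input out/cohort.csv --outdir out --seed 5 --bootstrap-B 499
```

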
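# Methods

## Model

Functional status is a continuous-time Markov chain on the state space
{0 = no disability, 1 = mild disability, 2 = severe disability, 3 = death},
graded from the ten BADL/IADL items (any BADL help → severe; intact BADLs
with any IADL help → mild).  The Markov assumption means the future depends
only on the current state and age, not on the disability history; this is a
known simplification (no individual frailty, no duration dependence).

Transition intensities follow a log-linear proportional-hazards form

    q_rs(age, z) = exp( β0_rs + βage_rs·(age − 65) + βf_rs·female + βr_rs·rural )

for each allowed arrow (r, s).  The reference profile is an urban man aged
65, so each baseline β0 is a log rate per person-year for that profile.
Two structures are built in: `full` (all six arrows among living states plus
the three living→death arrows) and `no-jump` (direct 0↔2 jumps forbidden).
The full structure is the default because it nests the alternatives; the
restricted variant remains available because the published arrow diagrams
for such studies are often restricted.  Age can enter either as a continuous
log-linear slope (default) or as 65–74 / 75–84 / 85–95 band indicators
(`age_form="bands"`); which of the two a given published analysis used is
usually not stated, so both are supported and neither is asserted.

## Likelihood for interval-censored panels

Living states are observed only at interview waves; deaths are exactly
dated (family-reported) but the state at the moment of death is unknown.
Between consecutive living observations (r at a₁, s at a₂) the contribution
is log P_rs(a₁, a₂).  A death at age d after a last living observation in
state r at age a contributes log Σ_{j∈living} P_rj(a, d) · q_{j,death}(d).
Subjects lost to follow-up contribute nothing after their last observation
(right censoring, assumed non-informative).  A wave recording both a living
state and a death age is invalid input and raises, never silently resolved.

P(a₁, a₂) is the product of matrix exponentials of Q frozen on cells of a
global age grid (default cell width 0.5 y, Q evaluated at cell midpoints,
so the freezing error is second order in the width).  Anchoring cells on a
global grid lets identical cells be computed once per likelihood
evaluation; the 4×4 exponentials are evaluated by a batched
scaling-and-squaring Taylor routine pinned to `scipy.linalg.expm` at 1e-12
in the tests.  Subjects are summed in id-sorted order (fixed, documented
summation order).

Fitting is L-BFGS-B on the negative log-likelihood with finite-difference
gradients, initialized at crude interval rates (transition counts divided
by person-time at risk, floored at 1e-4/yr, exact deaths attributed to the
last observed state).  Convergence status is always reported; the parameter
covariance is the inverse of a central finite-difference observed
information (relative step 3e-4).  Bootstrap CIs resample subjects (never
rows) with replacement, refit from the full-sample estimates, and take
2.5/97.5 percentiles; per-replicate failures are recorded and a failure
rate above 20% flags the interval unreliable.  Default B = 499.

## Life tables

Health expectancies integrate the transition probabilities over age,
e_rs = ∫ P_rs(a₀, u) du, by the trapezoidal rule on a 0.25-year grid up to
age 115 (both configurable).  The 115-year cap makes residual survival
negligible for realistic elderly intensities; a warning fires when the
survival probability at the cap still exceeds 1%, and a grid-convergence
test checks that halving the step moves every expectancy by < 0.5%.
Population-averaged rows weight the per-initial-state expectancies by the
stratum's empirical baseline state distribution (subjects entering within
±2.5 y of the index age).  Life-table CIs rerun the entire
resample→refit→integrate pipeline per bootstrap replicate, with the
empirical initial distribution recomputed on each resample.

## Onset Cox models

Disability onset merges mild and severe into one event.  Event time is the
gap from entry to the first wave observed disabled — the right endpoint of
the censoring interval; the midpoint convention is a plausible alternative
but the right endpoint is used and flagged here, interval-censored
refinements being out of scope.  Time-since-entry is the time scale with
entry age as a covariate (the adjusted models control for age, which rules
age out as the time scale).  Ties are handled by Breslow's method by
default because wave-synchronized times are heavily tied; Efron is
selectable.  Partial-likelihood maximization is delegated to statsmodels
`PHReg`; an independent hand-written Breslow partial likelihood serves as
the test oracle.  Missing covariate values become explicit "missing" dummy
levels so no record is dropped.

## PMM multiple imputation

Each incomplete baseline covariate is regressed on the other predictors
using a numeric working coding (age as-is, categoricals as ordinal level
indices); every missing value is replaced by the observed value of a donor
drawn uniformly from the k = 5 nearest neighbors in predicted score, so
imputed values are always legal observed categories.  One chained sweep
over variables is the default (configurable); m = 5 completed datasets are
generated from per-imputation seed substreams, and downstream results are
pooled by the plain entrywise mean.  This mean pooling is deliberately
non-standard relative to Rubin's rules — no between-imputation variance is
propagated — because it mirrors the sensitivity-analysis convention the
pipeline reproduces; it is a point-estimate smoother, not an inferential
procedure.

## Synthetic cohort generator

The generator emulates the design features of a CLHLS-like panel: entry
ages uniform on 65–95, waves at entry + 0/3/6/9/12 y, per-wave dropout 10%,
exact deaths reported only if the subject had not dropped out by the next
contact (keeping censoring non-informative), item-level covariate
missingness (default 0.2% per item, matching the low published missingness),
entry-state distributions per sex×region stratum echoing published
magnitudes, and covariate frequencies of the same order as the published
descriptive table.  Default true intensities rise log-linearly with age
and encode the reported phenomena — female excess disability incidence,
male excess mortality, rural recovery advantage — without claiming any
particular fitted values.  Trajectories are simulated Gillespie-style with
Q frozen over 0.1-year micro-cells (exponential holding times redrawn per
cell, exact for the cell-frozen process); a vectorized variant also
accumulates exact state-occupancy times, providing the trajectory-averaged
"true" life-table quantities written to the ground-truth sidecar.

What the generator does **not** emulate: survey weights and household
sampling structure, province stratification, proxy responses, questionnaire
content, and any non-Markov disability dynamics.  Passing tests therefore
demonstrate correctness of the estimators under the assumed model and
observation scheme, not robustness to model misspecification in real data.

## The designed calibration experiment

Parameter recovery and Wald coverage are verified on a purpose-built
scenario (`calibration_scenario`): n = 2000 subjects, 5 waves at 3-year
spacing, `no-jump` structure, age-homogeneous true rates of realistic
elderly-cohort magnitude (onset 0.15/yr, mild recovery 0.20, progression
0.12, severe recovery 0.15, mortality 0.06/0.10/0.30 from states 0/1/2),
female effects on onset (+0.25) and severe-state mortality (−0.30), a rural
effect on mild recovery (+0.20), balanced initial-state allocation (one
third per living state — the information-maximizing designed-experiment
allocation) and 5% dropout.  The experiment is age-homogeneous by design:
an a-priori Cramér–Rao analysis showed that with a continuous age slope the
age-65 reference intercepts are extrapolations whose information bound at
n = 2000 (SEs 0.13–0.35) cannot support tight recovery tolerances, whereas
the age-slope machinery itself is exercised by the exact simulator/matrix-
exponential cross-checks.  Under this design every parameter's standard
error is 0.06–0.12, and 20 replicates recover each baseline within 0.15 and
each effect within 0.2 at the required rate.  Wald coverage uses the same
scenario with all effects set to zero at n = 500 over 50 replicates.

## Numerical choices and degenerate inputs

- Matrix exponentials: batched scaling-and-squaring (scale to ∞-norm ≤ 0.5,
  degree-13 Taylor, square back); truncation error < 1e-13 at that norm.
- Transition matrices are validated row-stochastic within 1e-8; violations
  raise an internal-consistency error rather than propagating.
- Structurally impossible observed transitions yield −∞ log-likelihood with
  a diagnostic naming the subject and state pair.
- Zero observed transitions for an arrow produce a warning (weak
  identification) and the 1e-4/yr crude-rate floor keeps initialization
  finite.
- PMM donor pools are ordered deterministically (stable sort by distance)
  before the uniform donor draw, making imputations bit-reproducible for a
  given seed; a rank-deficient predictor matrix falls back to marginal
  donor draws with a logged warning.
- All stochastic components (generator, bootstrap, imputation) derive their
  streams from a single user seed via `numpy.random.SeedSequence` spawning.

## Problem sizes used in the automated checks

Oracle equivalences use 10^6 trajectories (path probability), 10^5
(occupancy), and a 2^16-step discretized chain; recovery uses 20 replicates
at n = 2000 and coverage 50 replicates at n = 500; the acceptance script
runs one n = 2000 pipeline plus n = 2000 Cox and n = 1500 imputation
demonstrations.  These sizes were chosen so the statistical tolerances are
comfortably inside Monte-Carlo error while the whole suite remains quick on
a single CPU.

## Known limitations

- Markov (memoryless) dynamics; no frailty or duration dependence.
- Exact transition times for living-state changes are never used even if
  known (interval-censored likelihood only).
- The Cox module is a conventional right-censored analysis of an
  interval-censored onset time (right-endpoint convention), matching common
  practice rather than an interval-censored PH estimator.
- Mean pooling of imputations understates uncertainty relative to Rubin's
  rules (offered as the documented default by design).
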
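# Methods

`seamsel` implements and evaluates a seamless hybrid phase II/III
two-arm trial design for time-to-event endpoints with a pre-identified
biomarker subgroup.  Stage 1 (phase II) compares a dichotomized survival
endpoint — alive or not at a landmark `t*` — and selects the population to
carry into stage 2 (phase III): the full population F, the subgroup S, both,
or neither (futility).  Stage 2 is analyzed with one-sided log-rank tests,
and stage-1 information enters the final test through a conditional error
function so that the family-wise type I error is controlled despite the
data-driven selection.

## Data model and simulator

Patients enter under uniform accrual (default 10/month across both arms)
and are randomized 1:1.  Subgroup membership is Bernoulli with prevalence
`tau` (default 0.7).  Event times are exponential: the control hazard is
`ln 2 / control_median` (default median 7 months), and treated hazards are
multiplied by `hr_S` inside the subgroup and `hr_SC` in the complement.
Censoring is administrative — follow-up is frozen at an analysis time —
plus an optional exponential loss-to-follow-up hazard (`ltfu_rate`,
default 0).  The phase II interim occurs when the last stage-1 patient has
completed `t*` months (default 12), so every stage-1 patient is evaluable
for the binary endpoint unless lost to follow-up earlier.

The binary endpoint codes a patient alive at `t*` as 1 (including anyone
still under observation at `t*`), dead before `t*` as 0, and a patient
censored alive before `t*` as excluded from the binary comparison.

Five packaged scenarios fix `hr_S` and a marginal full-population target
`hr_F`; the complement hazard ratio is derived by matching the 1-year
marginal survival of the treated full population,

    tau * S0(12)^hr_S + (1 - tau) * S0(12)^hr_SC = S0(12)^hr_F.

When `hr_F` is so unfavorable that no non-negative complement survival can
satisfy this (possible for `hr_F > 1` with a protective subgroup, as in the
packaged scenario 4), the derivation falls back to prevalence-weighted
hazard averaging, `hr_SC = (hr_F - tau*hr_S) / (1 - tau)`.  Scenario
fixtures also carry the selections considered acceptable and the
populations whose rejection counts toward overall power (scenario 4 counts
only S as a correct positive even though continuing with both populations
is acceptable, because the complement is harmed there; scenario 5
symmetrically counts only F).

If the trial continues, stage 2 enrolls `n_phase3` patients per arm from
the selected population (an enrichment cohort drawn entirely from S if only
S was selected), starting at the interim.  Stage-1 patients in the selected
population continue follow-up.  The final database lock is the entry of the
last stage-2 patient plus `followup_phase3` months (default 12); no rule
for the lock is canonical, and this choice gives stage-2 patients 12-40
months and stage-1 patients about 4-5 years of potential follow-up, so
stage-1 survival information is nearly complete at the final analysis.

### What the generator does not emulate

Real trials have non-constant hazards, informative censoring and dropout,
covariates beyond arm and subgroup, staggered or data-dependent accrual,
and imperfect biomarker assays.  Passing operating-characteristic tests
therefore demonstrates the internal frequency properties of the design
under a clean proportional-hazards world, not its behavior on any
particular real data set.  Proportionality holds exactly within S and
within SC but only approximately in their mixture F.

## Interim analysis

### Bayesian selection

The stage-1 binary outcomes follow a logistic regression

    logit P(alive at t*) = theta_0 + theta_S*S + theta_T*T + theta_TS*S*T,

so `theta_T` is the treatment effect (log odds ratio) in the complement
reference cell and `theta_T + theta_TS` the effect inside the subgroup.
The decision thresholds three posterior exceedance probabilities at an
effect threshold `zeta_e` (default 0):

| P(theta_TS > zeta_e) > tau_S | P(theta_T > zeta_e) > tau_F | decision |
|---|---|---|
| yes | yes | F & S |
| yes | no  | S if P(theta_T + theta_TS > zeta_e) > tau_1, else futility |
| no  | yes | F |
| no  | no  | futility |

Defaults: `tau_S = 0.5`, `tau_F = 0.7`, `tau_1 = 0`.  Comparisons are
strict, so boundary ties fall to the non-selection side; `tau_1` can only
convert subgroup continuations into futility stops, leaving the F and F&S
rates untouched.

### Priors

Three priors on `(theta_S, theta_T, theta_TS)` are provided:

- **peaked horseshoe** — `theta_k | lambda_k, tau ~ N(0, tau^2 lambda_k^2)`
  with local scales `lambda_k ~ C+(0,1)` and global scale
  `tau ~ half-t(df=1, scale=1)`;
- **flatter horseshoe** — same with global scale 10;
- **normal** — independent `N(0, 2)` (variance 2; the spread is one config
  scalar so a standard-deviation convention can be reproduced).

The global horseshoe scale is shared across the three coefficients by
default, the standard construction in which one parameter learns the
overall sparsity level; `global_shrinkage="per_coefficient"` instead gives
every coefficient an independent global scale, making the three marginal
priors independent.  The intercept always gets `N(0, 4)` — weakly
informative on the logit scale, covering control survival rates from under
2% to over 98% within two prior standard deviations.

### Posterior computation

The likelihood depends on the data only through four binomial cells
(subgroup x arm), so posterior evaluation is cheap.  Sampling uses the
`emcee` ensemble sampler with differential-evolution moves.  Two
reparametrizations remove the horseshoe funnel, which we found biases
ensemble samplers when the scales are kept explicit:

- per-coefficient global scales: both scales are integrated out
  numerically.  The product of the two half-Cauchy scales has the closed
  form density `(4/(pi^2 s)) ln(k/s) / ((k/s)^2 - 1)`, and the resulting
  1-D normal scale-mixture marginal is tabulated once per prior family on a
  log grid (trapezoidal integration, monotone-cubic interpolation of
  `log m` over `log |theta|`, which is smooth through the integrable log
  singularity at zero).  The posterior is then sampled directly over the
  four coefficients.
- shared global scale (default): the local scales are integrated out the
  same way, leaving a 5-dimensional posterior over the coefficients and
  `log tau`.

Both forms were validated against a sampler-free oracle — draws from the
exact prior reweighted by the cell likelihood — and a scaled-down version
of that cross-check runs in the test suite.  Defaults: 400 warm-up and
1200 retained ensemble steps (16-20 walkers), thinned evenly to
`chains x draws` pooled posterior draws (default 2 x 500).  Split-Rhat over
walkers and an autocorrelation-based effective sample size are attached to
every fit; fits exceeding the Rhat bound (default 1.1) raise a warning and
are counted — never dropped — by the simulation engine.  Exceedance
probabilities are strict-inequality draw fractions, with
`P(theta_T + theta_TS > zeta_e)` computed from per-draw sums to preserve
the (typically negative) posterior correlation between main effect and
interaction.

### Frequentist comparator

Selection can instead threshold the one-sided pooled-variance two-proportion
z statistics of the binary endpoint in F and in S: both above their
thresholds selects F&S, only `z_S` above selects S, only `z_F` above selects
F, neither is futility (defaults `tau_F* = tau_S* = 0`; ties again do not
select).  Degenerate tables (pooled survival 0 or 1) carry no evidence and
score z = 0.  An unpooled-variance variant is available by flag.

## Final analysis

Let `Z1b` be the stage-1 binary z, `Z1` the stage-1 log-rank z at lock, and
`Z2` the stage-2 log-rank z, per population.  With inverse-normal weights
`w1 = sqrt(n_phase2 / (n_phase2 + n_phase3))`, `w2 = sqrt(1 - w1^2)`
(so `w1^2 + w2^2 = 1`), the combination statistic is `S2 = w1*Z1 + w2*Z2`
and the weighted stage-1 binary statistic is `s1 = w1*Z1b`.

Under the joint null, `(S2_F, S2_S)` is treated as bivariate standard
normal with correlation equal to the subgroup prevalence `tau` (a
`sqrt_tau` convention is available by config switch).  Since the design
never stops early for efficacy, the critical value `c2` depends only on
`alpha` and solves `P(max(S2_F, S2_S) >= c2) = alpha` by Brent root-finding
on the bivariate normal CDF, with the exact endpoints
`Phi^-1(1-alpha)` at correlation 1 and `Phi^-1(sqrt(1-alpha))` at 0.

Because only `Z1b` (not `Z1`) is observed at the interim, the final rule
conditions on `s1` through the assumed binary-survival correlation `rho`
(default 0.8, itself estimated by simulation, below): an individual null
is rejected iff

    Z2 > (c2 - rho * s1) / w2.

With `rho < 1` this conditional substitution is conservative (the
unconditional rejection probability under the null is below `alpha`).  When
both populations are tested, closed testing additionally requires the
intersection null to be rejected: the intersection p-value at
`Zmax = max(Z2_F, Z2_S)`,

    p_{S,F} = 1 - P(Z_F <= Zmax, Z_S <= Zmax | corr = tau),

must fall below the conditional threshold

    p_thresh = 1 - P(Z_F < (c2 - rho*s1_F)/w2, Z_S < (c2 - rho*s1_S)/w2 | corr = tau).

The intersection p-value is decreasing in `Zmax` and, by the Slepian
inequality, decreasing in the correlation.

The log-rank statistic is the standard observed-minus-expected sum with
hypergeometric variance at each distinct event time, signed so that better
treated survival is positive; it is computed by a vectorized counting
implementation and cross-checked against `lifelines` in the tests.

## Planning utilities

- `estimate_rho` simulates phase-II cohorts, pairs the binary z at `t*`
  with the log-rank z on the same patients at complete follow-up, and
  returns the Pearson correlation per population and scenario, averaged
  (default: F and S, all five packaged scenarios).  At the default design
  this calibration gives approximately 0.8, the `rho` default.
- `find_sample_size` grid-searches per-arm stage sizes with the
  frequentist design at thresholds 0 and planning correlation 1, requiring
  a false positive rate within the two-sided 5% budget under the null
  scenario and power near 0.8 under the common-HR-0.7 alternative.
- `estimate_hazard_ratio` reports the exponential (constant-hazard) MLE
  rate ratio by default — exact for the simulation model and fast — or a
  Cox partial-likelihood fit (`hr_method="cox"`); the two agree closely on
  simulated data.  Bias summaries average estimated-minus-true hazard
  ratios over the trials in which a population was analyzed, using pooled
  stage-1 + stage-2 data at lock.

## Numerical and implementation choices

- Bivariate normal probabilities use `scipy`'s Genz CDF; correlations
  within 1e-12 of +/-1 switch to exact degenerate forms.
- `c2` values are cached per (correlation, alpha).
- One root seed drives everything: replicate seeds are spawned with
  `numpy.random.SeedSequence`, and each trial deterministically splits its
  stream into cohort, sampler, and stage-2 sub-streams, so any single
  simulated trial is replayable.
- Operating characteristics carry binomial Monte-Carlo standard errors for
  every percentage; decision percentages sum to 100 exactly.
- The acceptance script (`scripts/acceptance.py`) uses 1000 replicates for
  the frequentist null-scenario run, 200 replicates per prior (2 chains x
  500 retained draws) for the Bayesian runs, and 500 cohorts per scenario
  for the correlation calibration; these sizes keep a complete run to a few
  minutes on one CPU while leaving Monte-Carlo error well inside the
  tolerances used by the tests.

## Known limitations

- Only exponential event times and the four-cell covariate structure are
  supported; no stratified log-rank, multi-arm extension, or
  sample-size re-estimation.
- Post-selection hazard-ratio estimates are the naive MLEs; selection-bias
  corrected estimators are out of scope.
- Continuation with the complement alone (dropping S) is not offered.
- The conditional-error rule substitutes `rho * Z1b` for the unobserved
  stage-1 survival statistic; misspecifying `rho` downward lowers the final
  thresholds and inflates the realized type I error (the engine exposes
  `rho` so this sensitivity can be simulated directly).
- With heavy shrinkage the interaction exceedance probability concentrates
  near 0.5, so null-scenario selection splits are knife-edge and
  Monte-Carlo error in the posterior probabilities smears decisions near
  the thresholds; the defaults keep that smearing small relative to the
  replicate-count noise of the operating characteristics.
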
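# Methods

`initsurv` implements a longitudinal survival-and-causal analysis of
substance-use initiation in an adolescent cohort: construction of
counting-process (start–stop) interval data from visit-level records,
univariate and multivariable time-varying Cox proportional hazards models
with participant-clustered robust variance, LASSO-based predictor
screening, and marginal structural models (MSMs) estimated with stabilized
inverse-probability-of-treatment weights (IPTW). Because the motivating
cohort data are access-controlled, the package ships a synthetic cohort
generator with fully known causal structure; every statistical guarantee
the test suite asserts is a property of the methods evaluated against that
known truth.

## Outcome derivation

Initiation outcomes are derived per substance from visit-level endorsement
items collected by two sources (annual assessments and interim phone
interviews). The two sources are concatenated and ordered by a fixed study
visit order (baseline < 6-month phone < 1-year follow-up < … < 4-year
follow-up). Responses are coerced to {0, 1}; any other code (refusals,
"don't know") becomes missing. Endorsements flagged as occurring
exclusively in religious or ceremonial contexts are set to missing before
aggregation, so a later unflagged endorsement defines initiation instead.

The event time T is months since baseline at the first affirmative visit on
or before the 4-year follow-up; missing responses are skipped, never
treated as 0. Non-initiators are censored at their last observed visit;
control (case–control phenotype) status additionally requires a documented
observation at the 3-year follow-up, otherwise the status is *missing*
(the censored survival record remains usable). A baseline endorsement is
retained as an event at T = 0.5 months rather than T = 0: a zero-length
follow-up contributes no risk set, and 0.5 months (about two weeks) is the
smallest interval the months time scale resolves meaningfully. This value
is configurable.

One ambiguity is worth recording: when the 4-year visit itself is missing,
a phone endorsement between the prior annual visit and the 4-year window
still counts if it is observed; non-initiators are censored at the last
observed contact, whatever its type.

## Start–stop intervals and leakage control

Each participant's visits at months t₁ < … < tₙ (all ≤ T) become intervals
with startᵢ = tᵢ (0 for the first) and stopᵢ = tᵢ₊₁, the last interval
ending at T; the event indicator is 1 only on the final interval of an
event participant; intervals with stop ≤ start are dropped. If the first
observed visit falls after time 0 a baseline row anchored at 0 is
prepended, copying the earliest observation's covariates. Intervals are
half-open [start, stop) with events at stop; when an event time ties a
visit time, the covariate value comes from the earlier visit (no
look-ahead). Times are kept as floating months without rounding.

Covariates are carried forward within participant (LOCF); no back-filling.
Intermittently missing numeric predictors use a value + availability
encoding: an indicator X_obs (1 if the — possibly carried-forward — value
is observed) plus median imputation of the remaining gaps, the median
pooled over all participants and visits. Forward-fill precedes the
encoding, so the indicator marks "not yet measured for this participant"
rather than single skipped items; per-visit medians are available behind a
flag. A metamorphic test perturbs covariates at random visits and asserts
that only interval rows with start ≥ the perturbed time change.

## Predictor QC

Before modeling: drop entirely-missing columns; drop near-constant numeric
columns (modal frequency ≥ 0.99 — threshold configurable); among pairs
with pairwise-complete |Pearson r| > 0.9, drop the later column in input
order, visiting pairs by descending |r| for determinism; and require that
a predictor be observed at least once in ≥ 50% of participants. Forced
covariates (sex, baseline age, site, ancestry PCs) and polygenic scores
are exempt. The pipeline is idempotent and column-order permutation can
change which member of a collinear pair survives but never the number
kept.

## Time-varying Cox models

The univariate screen fits, per candidate predictor, the hazard
h_i(t) = h₀(t) · exp(βX_i(t) + γᵀC_i) with C_i = sex, baseline age, site
indicators and 20 ancestry PCs. The multivariable model stratifies the
baseline hazard by study site, h₀,site(t), keeps the forced covariates,
and includes the selected predictors with their availability indicators.

The partial likelihood is the counting-process Breslow objective: the risk
set at event time t comprises intervals with start < t ≤ stop within
stratum. Breslow tie handling was chosen because ties on a months scale
are frequent but shallow and the objective then coincides with the
explicitly written risk-set product used as an independent brute-force
oracle in the tests (Nelder–Mead/Powell maximization of the literal
double-loop likelihood; agreement to 1e-6 on small datasets). The fitter
is Newton–Raphson with step-halving on centered covariates; a fit is
flagged non-converged when iterations exhaust or a coefficient moves the
linear predictor by more than 10 SDs of its covariate (the practical
signature of monotone likelihood). Variance is the participant-clustered
sandwich built from Lin–Wei score residuals aggregated by id; the
implementation reproduces `survival::coxph(..., ties="breslow",
cluster(id))` — coefficients, naive and robust SEs, with and without
strata — to ~1e-10 on a reference dataset, and that cross-check runs in
the suite via Rscript.

Multiplicity: Benjamini–Hochberg q-values and Bonferroni-adjusted
p-values are computed across the family of converged univariate fits;
non-converging predictors are excluded from the family size m and logged.
Pre-selection keeps predictors with screening p ≤ 0.05 (configurable; the
threshold is a package default, not an externally fixed constant) that
also pass the coverage filter.

LASSO screening treats each interval's end time as a right-censored
observation time — the standard approximation when the penalized solver
does not handle late entry; it is used only to shortlist predictors, never
for effect estimates. Forced covariates carry penalty factor 0. The
penalty is chosen at minimum cross-validated deviance with folds grouped
by participant (10 folds, seeded); held-out deviance is evaluated with the
package's own Breslow log-likelihood. A zero penalty degenerates to an
unpenalized fit and retains everything; an all-zero selection yields a
forced-covariates-only final model with a warning.

In univariate screens site enters as fixed-effect indicators and in the
multivariable model as strata; both options are available in either place.

## Marginal structural models with stabilized IPTW

For a binary exposure A_ik (continuous exposures are median-split among
observed values, ties at the median coded 0), stabilized weights are

SW_ik = ∏_{m≤k} P(A_im | A_{i,m−1}, Z_i, t_im) /
               P(A_im | A_{i,m−1}, Z_i, t_im, L_im),

with both probabilities from logistic regressions; prior treatment is 0 at
each participant's first interval. The time term is a restricted cubic
spline with 4 knots at the 5/35/65/95 percentiles of interval end times
(degrading to linear when fewer than three distinct knots exist).
Estimated probabilities are clipped to [0.01, 0.99] and weights truncated
at their 0.99 quantile; exposures with person-interval prevalence outside
[0.05, 0.95], mean weight outside [0.9, 1.1], or effective-sample-size
ratio (Σw)²/(n·Σw²) below 0.5 are excluded from outcome modeling and from
the FDR family. All thresholds are package defaults, configurable and
recorded in run manifests.

The outcome model is a weighted pooled logistic regression
logit P(Y_ik = 1) = α(t_ik) + ψA_ik + ηᵀZ_i fitted by GEE with an
independence working correlation, so standard errors are
participant-clustered by construction. ψ is a causal log-odds ratio; with
rare per-interval events it approximates a log hazard ratio. BH q-values
are computed across retained exposures only.

Denominator confounders L are declared per exposure in configuration and
use the same forward-filled, leakage-free values as the Cox stage.

## Synthetic cohort generator

The generator emulates the structure of a multi-site adolescent cohort
with a ~4-year schedule of annual and mid-year contacts (months 0, 6, …,
48): baseline age in months ~ Normal(118.9, 7.4) (i.e. 9.91 ± 0.62
years), sex ~ Bernoulli(½), site uniform over 5 sites, 20 standard-normal
ancestry PCs and 4 polygenic scores. A time-varying confounder follows an
AR(1) process (ρ = 0.5, innovation SD √(1−ρ²) so the stationary variance
is 1 when feedback is off) with exposure feedback κ·A_{k−1}; exposure is
Bernoulli with logit a₀ + a₁L_k + a₂A_{k−1} + a₃ᵀZ; events are discrete-
time Bernoulli draws per interval with logit α₀ + α₁t + ψA_k + δL_k +
ηᵀZ. First-endorsement items switch to 1 from the first post-initiation
visit onward; optional flags mark religious-context-only endorsements.
Missingness is MCAR at the visit level (baseline always retained; monotone
dropout optional, default off) and at the cell level, 10% each by default.
The target event rates are matched by calibrated hazard intercepts
(−4.392 for the 36.5% "alcohol-like" outcome, −6.602 for the 5.44%
"nicotine-like" outcome, slope 0.015/month), solved by root-finding on a
200,000-participant simulation and then frozen.

`SimTruth` records ψ, per-outcome cumulative incidence, and a Monte-Carlo
counterfactual marginal odds ratio: the cohort is re-simulated (10⁵
participants, seed offset +1) under do(A ≡ 1) and do(A ≡ 0) and the pooled
person-interval event odds compared. Two caveats define what this number
means: it is the *total* effect of the sustained regime, so with κ·δ ≠ 0
it exceeds exp(ψ) through the exposure→confounder→outcome path; and odds
ratios are non-collapsible, so it approaches exp(ψ) only in the rare-event
regime. The generator's default per-interval probabilities are kept small
for exactly this reason.

What the generator does not emulate: real instrument content, genotype or
LD structure, informative missingness, site-level covariate shifts, and
measurement error — so passing tests demonstrate correctness of the
estimation machinery under the stated model, not robustness to violations
of it.

## Reference feedback simulation and evaluation studies

The `experiments` module fixes a reference treatment–confounder feedback
setting used by the recovery, null-calibration and sensitivity studies:
a = (−0.4, 0.6, 0.3, (0.2, 0.1)), κ = 0.3, δ = 0.8, ρ = 0.5, ψ = log 2,
baseline hazard (−5.3, 0.01) giving per-interval event probabilities
around 0.01. Two considerations shaped it. First, weight truncation at the
0.99 quantile deliberately trades a small confounding bias for variance;
under very strong confounding (a₁ = δ = 1) that residual bias reaches
+0.13 on the log-odds scale, while the chosen setting keeps it near +0.05
— the sensitivity study confirms conclusions are stable across clip
{0.001, 0.01} × truncation {0.99, 0.995}. Second, the MSM models the
current exposure only; with strong exposure autocorrelation part of the
A_{k−1}→L_k→Y path loads onto ψ̂. Moderate autocorrelation (a₂ = 0.3)
keeps that contamination small. History-augmented or cumulative-exposure
MSMs, which would remove it, are out of scope. The naive contrast
estimator (pooled logistic adjusted for baseline covariates only) is
biased upward by roughly +0.47 under the same conditions, an order of
magnitude more than the IPTW estimator.

Problem sizes are desk-scale by design: Cox recovery uses 50 replicates of
n = 2000; the permutation null 500 refits at n = 300; MSM recovery 100
replicates at n = 3000; the type-I study 200 replicates at n = 1200 —
chosen because participant-clustered sandwich errors are anticonservative
with materially fewer events per replicate (~60 events: empirical size
0.08) and the truncated-weight test grows conservative at much larger n
(0.02–0.03 at n = 1500); at n = 1200 (~90 events) the empirical size sits
at the nominal 0.05. The Bonferroni family-wise-error study screens 20
null predictors in each of 100 replicates.

## Numerical choices and degenerate inputs

Covariates are centered before Newton iterations; linear predictors are
clipped at ±200 inside the exponential only as an overflow guard.
Constant columns raise an error in `fit_tv_cox` and are dropped with a
warning by the multivariable wrapper (e.g. an all-ones availability
indicator). Zero events, empty visit lists, negative follow-up, visits
predating baseline, unknown visit labels, and all-missing exposures all
raise typed errors naming the offending field or label. Convergence uses
both a step-norm (1e-9) and a relative-gradient criterion; the LASSO path
uses scikit-survival's coxnet with alpha_min_ratio 0.01.

## Known limitations

- No censoring weights (IPCW): dropout is assumed MCAR, matching the
  generator; informative dropout would bias both Cox and MSM stages.
- Interval-by-interval MSM only; no cumulative or lagged exposure effects.
- LASSO screening ignores late entry by construction (documented
  approximation; exact start–stop screening is available only through the
  unpenalized screen).
- Breslow ties are slightly conservative relative to Efron when ties are
  heavy relative to risk-set size.
- The Bonferroni/BH family covers converged fits only; heavy
  non-convergence would shrink the family and is therefore logged.
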
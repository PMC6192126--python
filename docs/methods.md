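# Methods

## Problem and design

`portaldid` studies whether adopting an electronic patient portal changes a
patient's primary-care utilization (completed PCP office visits) and
appointment adherence (no-shows, cancellations).  The design is a panel
difference-in-differences (DID) with *staggered* event times: each patient
has their own clinic-enrollment quarter (`NewIndex`, the first "New" PCP
visit) and, for adopters, their own treatment quarter (`AdoptIndex`, portal
activation).  The study window is 12 calendar quarters, t = 0 (Y13Q3) to
T = 11 (Y16Q2).

Two features distinguish the model from a plain event study:

1. **Disease-process lags.**  New patients arrive because of a triggering
   health condition, so utilization spikes around the new visit and decays
   as the condition resolves.  Because portal activation typically happens
   at or right after the new visit, this natural course is confounded with
   the treatment clock.  The model separates the two clocks with
   disease-lag dummies D_ik(t) = 1 iff t − NewIndex_i = k (both groups) and
   treatment-lag dummies P_ik(t) = 1 iff t − AdoptIndex_i = k and the
   patient is a user.
2. **Time-varying disease burden.**  The active problem number (APN, the
   count of problems on the EMR active problem list) enters as a
   three-category time-varying covariate, because users' and non-users' APN
   paths diverge even after baseline matching.

The count model for outcome Y_it is a log-link GLM,

    log E[Y_it] = γ·User_i + Σ_τ λ_τ·Time_iτ(t) + Σ_k θ_k·D_ik(t)
                  + Σ_k β_k·P_ik(t) + α·APN_it + η·X_i ,

with Poisson variance inflated by a dispersion φ (quasi-Poisson).  exp(β_k)
is the user/non-user rate ratio attributable to the treatment at the k-th
quarter post adoption.

## Cohort rules

Patients are partitioned into **users** (activated in-window, still active
at the end), **consistent-users** (activated before the window),
**temporary-users** (inactive before the end) and **non-users** (never
registered).  The primary cohort keeps users and non-users whose new visit
(and, for users, activation) falls strictly after t = 0; consistent- and
temporary-users are excluded.  Each patient's **baseline** is the quarter
before the earlier of new visit and activation; baseline APN is discretized
0 / 1–4 / 5+, baseline arrived visits 0 / 1 / 2+, baseline no-shows and
cancellations 0 / 1+.

**Matching.**  The probability of becoming a user is estimated by logistic
regression on the demographics (age group, sex, race, marital status,
insurance) plus the four baseline categories.  Non-users are matched 1:1 to
users by greedy nearest-neighbor on that score, without replacement, exact
on the new-visit quarter by default (a flag disables stratification), no
caliper by default.  Users are processed in descending score; distance ties
break to the lowest non-user id.  On (quasi-)separation the logit falls
back to a lightly ridge-penalized fit with a warning.  Balance is reported
as level counts, column percentages and Pearson chi-square p-values
(no continuity correction) for the unmatched and matched cohorts.

## Estimation

Point estimates are Poisson maximum likelihood via iteratively reweighted
least squares (with the canonical log link, Fisher scoring is exact Newton).
The implementation is in-package and deliberately lean — the evaluation
studies and the pair bootstrap refit the same design thousands of times —
and is verified in the tests against statsmodels' GLM (agreement ~1e-8) and
against direct numeric likelihood maximization (1e-6 on small instances).
Overdispersion is handled quasi-likelihood style: φ̂ = Pearson X²/(n − p)
scales the inverse Fisher information; point estimates are untouched.
Inference is two-sided Wald at 0.05.

Reference levels: the τ = 0 time dummy is absorbed into the intercept; APN
category "0" and the alphabetically first level of each demographic are
references.  Design columns with zero support (e.g. treatment lags
reachable only by the earliest adopters) are dropped and reported as
absent, never imputed.  The design keeps the user main effect γ and drops
the τ = 0 dummy.  Rows run from each patient's baseline quarter through T;
pre-relationship quarters carry no defined clinic relationship (a
full-window mode is available by flag).  No clustering adjustment beyond
the dispersion scale is applied by default.

## The Ω (omega) no-show test

The per-appointment no-show **rate** is no-shows over appointments
scheduled.  A per-appointment logistic model would treat one patient's
appointments as independent, which they are not; instead two count models
are fitted on one shared design: Y = event count (no-shows) and
Z = scheduled − Y (appointments made that were not the event).  With
treatment-lag coefficients β_k (Y model) and b_k (Z model),

    Ω_k = exp(β_k − b_k) = ρ¹/ρ⁰ ,   ρ = E[Y]/E[Z] ,  rate = ρ/(1+ρ) ,

and Ω_k < 1 if and only if the treated/counterfactual rate ratio is below 1
(the map ρ ↦ ρ/(1+ρ) is strictly increasing; the tests assert the sign
equivalence exhaustively on a grid).  Cancellations are tested the same way
with Y = cancellations.

**Denominator.**  Appointments scheduled = arrived + no-show + cancelled,
so Z(no-show) = arrived + cancelled and Z(cancelled) = arrived + no-show —
symmetric across the two analyses.  An alternative mode excludes
cancellations from the no-show denominator.

**Inference for β_k − b_k.**  The two fits share data and are correlated.
Default: nonparametric bootstrap over matched pairs (patients resampled as
pairs, both models refitted per replicate, 500 replicates by default,
seeded), percentile intervals, two-sided inversion p-value with the usual
(+1)/(B+1) correction.  A faster approximation stacks the per-patient score
influence functions of the two fits to get the joint covariance
("delta" mode); the two agree well in the tests.  Bootstrap replicates that
lose support for a lag column are dropped for that lag; a run errors out if
fewer than half the replicates succeed.  Implied reference rates are
evaluated for a user at reference covariates at the modal adoption quarter
plus k (logged in the output).

## Synthetic cohort generator

No patient-level data is deposited with the study, so the generator is the
pipeline's data source and defines the study conditions.

* **Demographics** are drawn from the published non-user column
  percentages (five variables, 2–9 levels).  **Adoption** is Bernoulli in a
  logistic model whose default log-odds reproduce the published selection
  pattern (middle-aged, female, married more likely; children, Black race,
  Medicaid/Medicare less likely), targeting ~26% adopters.
* **Timing.**  `new_index` is uniform on 1..T−1.  Activation happens at the
  new visit or right after: lag geometric with mean 0.5 quarters, truncated
  at T.  Among adopters, 10% are pre-window activations (consistent-users)
  and 5% deactivate (temporary-users); both are excluded by the primary
  inclusion rules and matter only for the sensitivity scenarios.
* **Disease burden.**  APN starts at a Poisson(1.5) draw at baseline and
  accrues independent Poisson increments per quarter — 0.55 for eventual
  adopters vs 0.40 for non-users, reproducing the published divergence.
  The start value is drawn rather than fixed at zero because the published
  baseline APN distribution is non-degenerate (36/46/17% across 0 / 1–4 /
  5+) and matching on a constant would be vacuous.
* **Counts.**  Arrived, no-show and cancelled are three conditionally
  independent draws per patient-quarter sharing the time, disease-lag, APN
  and demographic structure, each with its own intercept (default
  quarterly rates 0.18 / 0.040 / 0.050 at reference — the no-show level
  matches 0.14–0.20 per patient-year) and its own treatment-lag vector.
  Default treatment truths: one *volume* vector shared by arrived and
  cancelled follows the published arrived-visit trajectory (1.330 at
  adoption fading to ~0.80 at lags 7–8), and the no-show vector adds the
  published per-appointment odds trajectory (0.663 at adoption, …) on top
  of it.  Because arrived and cancelled share one vector, the complement
  count Z = arrived + cancelled is exactly log-linear, the generated
  no-show Ω_k equals the stated odds ratios, and the cancellation rate is
  (nearly) unaffected — the qualitative pattern the design targets.
  Variance is φ·mean via a negative binomial with size μ/(φ−1) and success
  probability 1/φ (φ = 1.5 by default), so the quasi-Poisson dispersion
  estimate targets φ directly.
* **Reproducibility.**  All randomness flows from one seed through
  counter-based (Philox) per-patient substreams keyed by patient id, so
  cohorts are bit-reproducible and invariant to patient reordering.

What the generator does **not** emulate: real EMR marginals beyond the
printed table, portal-message traffic, deactivation dynamics, geographic or
insurance-network structure, and any misspecification of the count model
(the generated mean structure is exactly the fitted one).  Passing
recovery/calibration tests therefore demonstrates correctness of the
estimator and pipeline, not robustness to model misspecification in real
data.

## Evaluation studies and problem sizes

* **Parameter recovery** — 200 cohorts of 6,000 patients with
  β₀ = log 1.3, β₇ = log 0.82, φ = 1.5: mean bias of β̂₀ and empirical 95%
  CI coverage (binomial band 0.91–0.985 at 200 replicates).  Fits are
  warm-started across replicates; this changes only iteration counts.
* **Ω null calibration** — no treatment effect on either paired response;
  150 replicates of 600 patients, 200 bootstrap draws each.  With the extra
  Monte Carlo error at 150 replicates the acceptance band is 0.013–0.10
  (the 200-replicate band is 0.02–0.09).  Event intensities are raised
  (no-show intercept log 0.2) so the small per-replicate cohorts carry
  informative counts.
* **Ω recovery** — one cohort of 10,000 patients with an exact generated
  Ω₀ = 0.66; the conditions (50% adopters, no-show intercept log 0.25) are
  set so that se(Ω̂₀) ≈ 0.02, the precision the single-run ±0.05 check
  presumes.  Verified unbiased across 20 replicates during development.
* **Balance restoration** — 5,000 patients under the default selection:
  chi-square rejects pre-match for each of the five selection-driving
  demographics and at least 8 of 9 matched covariates are balanced
  post-match.

## Numerical notes and edge cases

* IRLS converges on relative deviance change < 1e-10 (100 iterations max);
  linear predictors are clipped at ±30 to guard overflow in degenerate
  iterations.  Rank deficiency is detected up front and reported with the
  collinear column names (QR with column pivoting).
* Dispersion is constrained to φ ≥ 1 in the generator; the fit itself does
  not constrain φ̂.
* Empty categorical cells in balance tables are dropped with a log note;
  chi-square is skipped (NaN) for degenerate tables.
* `n_patients = 0`, single-class propensity inputs, negative counts,
  inconsistent adoption histories and missing quarter rows all raise typed
  errors naming the offending patient/field.
* Scenario runs never mutate their inputs; re-running the baseline after
  any scenario reproduces it exactly.

## Known limitations

* The three-year professional-services lookback that defines "new patient"
  cannot be evaluated inside a 12-quarter window; `new_index` is taken as
  given (the generator assigns it; a real-data adapter must supply it).
* Temporary-user detection uses an active-at-end flag, not login telemetry.
* The choice of variance estimator for β̂_k − b̂_k (pair bootstrap) is a
  package decision; the delta mode is provided as a cross-check.
* No negative-binomial or zero-inflated likelihoods in the headline path,
  and no per-appointment logistic model (rejected by design).
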
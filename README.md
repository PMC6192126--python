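# portaldid

Panel difference-in-differences analysis of how adopting an electronic
patient portal changes primary-care utilization and appointment adherence.

## The problem

Patient portals (secure messaging, record access, appointment management)
are hypothesized to change how patients use primary care.  Measuring that
effect from EHR data is confounded twice over: patients activate the portal
at or right after the clinic visit triggered by a new health problem, so
the natural course of that problem masquerades as a portal effect; and
sicker patients both adopt portals more and visit more.  `portaldid`
implements a causal pipeline for this setting:

1. **Synthetic cohort generator** — a 12-quarter (Y13Q3–Y16Q2) new-patient
   cohort with covariate-dependent portal adoption, staggered new-visit and
   activation quarters, diverging disease-burden (active-problem-number)
   paths, and overdispersed counts of PCP appointments arrived / no-show /
   cancelled.  No patient-level data is deposited with the study the design
   follows, so the generator is the pipeline's data source.
2. **Cohort preparation** — user / consistent-user / temporary-user /
   non-user classification, inclusion criteria, per-patient baseline
   quarter (the quarter before the earlier of new visit and activation),
   and baseline discretization (APN 0 / 1–4 / 5+; arrived 0 / 1 / 2+;
   no-show and cancellation 0 / 1+).
3. **Propensity matching** — logistic adoption propensity on demographics
   plus the baseline profile; greedy 1:1 nearest-neighbor matching without
   replacement, exact on the new-visit quarter; chi-square balance tables.
4. **Panel DID** — for patient i at quarter t, with per-patient enrollment
   time NewIndex and treatment time AdoptIndex,

       log E[Y_it] = γ·User_i + Σ_τ λ_τ·Time_iτ(t) + Σ_k θ_k·D_ik(t)
                     + Σ_k β_k·P_ik(t) + α·APN_it + η·X_i

   where D_ik(t) = 1 iff t − NewIndex_i = k (disease-process lag) and
   P_ik(t) = 1 iff t − AdoptIndex_i = k for users (treatment lag).  The fit
   is Poisson ML with quasi-Poisson (Pearson) dispersion; exp(β_k) is the
   users/non-users rate ratio k quarters post adoption.
5. **Ω no-show test** — the same model is fitted to the event count Y
   (no-shows) and the complement Z (appointments scheduled that were not
   the event); Ω_k = exp(β_k − b_k) compares the per-appointment no-show
   odds, and Ω_k < 1 iff the no-show **rate** ratio is below 1.  CIs and
   p-values come from a matched-pair bootstrap (or an influence-function
   delta mode).
6. **Sensitivity scenarios** — redefining users as ≥2-login patients, and
   folding pre-window adopters into the user group with adoption at t = 0.

See `docs/methods.md` for the model, generator and evaluation details.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # 6,000-patient cohort
python analysis/02_prepare_and_match.py   # inclusion, baseline, matching
python analysis/03_fit_panel_did.py       # arrived-visit panel DID
python analysis/04_noshow_cancellation_tests.py
python analysis/05_sensitivity_scenarios.py
python analysis/06_capacity_arithmetic.py
```

The generator's default treatment truths follow the published effect
trajectory (arrived-visit boost 1.33 at adoption fading to ~0.80 at lags
7–8; sustained no-show reduction; no cancellation effect), so a run
recovers numbers of that shape.  With the committed seed (1) the scripts
print, among other things:

```
simulated 6000 patients, 45477 patient-quarters
portal status classification:
  non-user           4358  (72.6%)
  user               1392  (23.2%)
  consistent-user     151  (2.5%)
  temporary-user       99  (1.6%)

matched 1392 pairs (0 users unmatched)
covariates balanced after matching: 9/9

panel: 20422 patient-quarter rows over 2784 patients
Pearson dispersion estimate: 1.507
lag-k arrived-visit rate ratios (users/non-users):
  lag  0: 1.453 (1.311, 1.611)  p=0.000
  ...
  lag  8: 0.714 (0.530, 0.962)  p=0.027

  0  +0q | 1.453 (1.311, 1.611) <0.001 | 0.585 (0.453, 0.767) 0.007 | 0.915 (0.752, 1.144) 0.425

wasted slots per provider-year: 182-260 (0.14-0.2 x 1300 panel patients)
20% no-show reduction recovers 36-52 slots (~0.9/week)
```

Reading the output: the lag-0 rate ratio > 1 is the mechanical visit boost
at activation; the deficits around lags 7–8 are the longer-run reduction in
disease-burden-adjusted utilization; no-show Ω < 1 at adoption means
portal users miss a smaller share of their scheduled appointments than
matched non-users; and the capacity figures translate per-patient no-show
rates into appointment slots lost per provider panel per year.

The same pipeline is scriptable through the `portaldid` CLI
(`simulate`, `prepare`, `match`, `fit`, `noshow-test`, `scenario`,
`report`, `all`) from a YAML config with a recorded run manifest.

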
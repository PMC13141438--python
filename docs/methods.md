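# Methods

## The problem this package models

Corticosteroid use in ARDS is decided day by day in response to evolving
severity, and the outcome (hospital death) is terminal. Any honest analysis
of "does dose X at time T associate with mortality" must therefore handle
(a) time-varying confounding by indication, (b) a risk set that shrinks as
patients die or leave the ICU, and (c) thinning covariate overlap at high
doses and late times. The package implements the landmark sliding-window
design with overlap-weighted AIPW estimation, and — because real reference
data require credentialed access — ships a synthetic cohort whose causal
truth is computable, so the estimator can be held to account.

## Windowing and exposure conventions

* Day `d` covers hours `[24d, 24(d+1))` from ARDS onset; 13 windows with
  starts 0..12, each 3 days, labelled `"s-(s+2)"`.
* Eligibility (landmark rule): alive **and** under ICU observation through
  the window's end day. Patients discharged alive from ICU before the end
  day are ineligible for that and later windows; eligible patients keep
  their hospital-mortality outcome even if it occurs after ICU discharge.
* Exposure: cumulative PE dose over the 3 window days. Conversion factors:
  prednisolone/prednisone 1, hydrocortisone 0.25, methylprednisolone 1.25,
  dexamethasone 5/0.75. A dose exactly at the threshold counts as treated;
  `0 < dose < threshold` rows are excluded from that contrast. Oral and
  intravenous routes share one conversion table.
* The 270 and 390 mg/3d anchors are approximate under the standard table
  (70 mg/day methylprednisolone → 262.5 mg/3d; 20 mg/day dexamethasone →
  400 mg/3d); the round printed thresholds are used, not back-solved values.
* Pre-ARDS steroid exposure (72 h before onset) is banded none / <45 /
  45–<120 / ≥120 mg PE and enters the models as dummies. Exactly 120 mg
  goes to the top band (the published band edges leave it unassigned).
* Dynamic covariates per window: mean, range, sample variance (n−1; zero
  when one observation), **last observed value**, and an all-missing flag,
  after LOCF ≤48 h (never for arterial-blood-gas variables). The last-day
  value is included because the latent severity process is Markov: the
  window-end state is what carries into follow-up, and without it the
  covariate set would have built-in residual confounding no estimator could
  remove. LOCF is applied before summarising (assumption; the source
  convention is unstated).
* Corticosteroid-history terms: cumulative PE from day 0 to window start
  and an any-steroid-in-the-prior-3-days flag, plus the pre-ARDS bands.

## Estimators

With cross-fitted `ê, m̂₁, m̂₀` and overlap weights `w = ê(1−ê)`:

* **OWRD (primary)**: outcome-contrast term `Σw(m̂₁−m̂₀)/Σw` plus per-arm
  self-normalised (Hájek) residual corrections
  `Σ A(1−ê)(Y−m̂₁)/Σ A(1−ê) − Σ (1−A)ê(Y−m̂₀)/Σ (1−A)ê`.
  A pooled-denominator variant (all terms over `Σw`) is available via
  `normalization="pooled"`; the two coincide for constant `ê` and are
  asymptotically equivalent, but the pooled form can explode on small cells
  with saturated propensities, which is why the arm form is the default.
* **SE**: empirical standard deviation of per-row influence contributions
  (ratio-linearised) divided by √n; 95% CI normal. A percentile bootstrap
  (`bootstrap_ci`, 500 draws) is available.
* **Sensitivity**: standard AIPW ATE with Hájek-stabilised weights and
  propensity truncation at 0.01 / 0.05; shock exclusion (any recorded
  noradrenaline > 0.15 µg/kg/min) and pulse exclusion (>1000 mg PE in any
  window) drop patients before framing.
* **Double robustness, stated precisely**: a correct propensity model makes
  OWRD consistent for the overlap-population risk difference whatever the
  outcome model; a correct outcome model alone makes it consistent for the
  fitted-weight average of the true conditional effect, which equals the
  target when the effect is homogeneous or null. The double-robustness test
  therefore uses a null data-generating process, where both directions hold.
* **Exact balance**: when `ê` is a maximum-likelihood logistic fit, the
  overlap balancing weights (1−ê on treated, ê on controls) equalise
  weighted covariate means between arms *exactly* (score equations); this is
  used as a hard 1e-6 numerical oracle. The MLE path standardises columns
  internally and uses Newton iterations (statsmodels) because quasi-Newton
  stopping rules cannot guarantee that tolerance.
* Degenerate cells (< 5 patients in either arm by default; configurable to
  0) are reported as unestimated with a reason, never fabricated.

## Nuisance models

Learners: unpenalised logistic GLM, elastic-net logistic (path by inner CV),
random forest (500 trees, min leaf 10), shallow gradient boosting
(depth 2, 200 rounds, rate 0.05). Outer 5-fold stratified cross-fitting;
per-training-fold ensemble weights minimise inner-CV negative log-likelihood
over the probability simplex by exponentiated gradient (tol 1e-8);
byte-identical learners collapse their weight onto the first. The outcome
model is fit on the pooled frame with treatment as a feature and toggled for
`m̂₁/m̂₀` (arm-specific fits are an option but are unstable in late windows).
Predictions are clipped to [1e-6, 1−1e-6]. Everything is seeded.

## Imputation and pooling

Remaining missing covariates are imputed per window frame by chained
equations: continuous columns by a Bayesian linear draw (posterior
coefficient draw + residual noise), binary columns by a logistic Bernoulli
draw; M = 5 copies, 10 sweeps by default (conventional values; the source's
settings are unpublished). Estimates are computed per copy and pooled by
Rubin's rules with a normal-reference CI (not Barnard–Rubin df; negligible
at these sizes). With no missing cells the stack collapses to one copy, so
the pooled estimate equals the single-frame estimate exactly.

## The synthetic cohort

Structure (defaults chosen to emulate an unselected ~1000-patient ARDS
cohort: ~39% treated, of whom roughly 77/59/45% reach the 150/270/390
tiers in some window; hospital mortality ~26%, ICU mortality ~22%, median
ICU stay ~10 days, ~16% pre-ARDS steroid users):

* Latent severity `S_d`: AR(1) (persistence 0.8, noise SD 0.5, recovery
  drift −0.04/day) around a frailty `u` that is a deterministic function of
  age and comorbidities — deliberately, so the baseline covariates carry all
  patient-level heterogeneity and sufficiency is achievable.
* Observables: noradrenaline dose and PEEP are complete and monotone in
  `S_d` (noradrenaline noiseless, making the window-end state observable);
  P/F, lactate, creatinine, white cells are noisy monotone maps with
  missing-at-random gaps whose rate halves when noradrenaline > 0.05
  (sicker patients get more labs). P/F (and optionally other ABG variables)
  is never LOCF-carried.
* Treatment: daily logistic initiation/continuation on current severity,
  previous-day treatment, pre-ARDS use and chronic lung disease; daily PE
  dose = 30 mg floor + severity-escalating log-normal; drug identity drawn
  0.5/0.3/0.15/0.05 over methylprednisolone/hydrocortisone/prednisolone/
  dexamethasone.
* Death: daily Bernoulli hazard on severity (ICU); severity-dependent
  geometric-type discharge from day 3; small severity-dependent ward
  mortality after discharge, so hospital > ICU mortality.
* Treatment effect: either per-day additive increments to the daily hazard
  from first exposure onward (`hazard` mode, for late-harm patterns), or a
  one-off additive surcharge on the terminal death risk of exposed ICU
  survivors, read from a per-day schedule at the first exposure day
  (`terminal` mode). Zero effect is exactly representable; with zero effect
  and no severity feedback, potential outcomes are identical pathwise.
* Policy coefficients may be −∞ (never treat) and hazard intercepts −∞
  (no deaths) to express degenerate worlds; NaN and +∞ are rejected.

**The oracle** (`true_ato`) defines the estimand at latent-state
granularity: draw subjects, keep those truly eligible under the natural
regime, and per subject run an inner conditional Monte Carlo from the
pre-window state — natural draws give the true window propensity
(conditional on surviving and staying through the window, and excluding the
intermediate-dose band), forced-exposure/forced-control draws with shared
severity innovations give `r₁, r₀` with hospital-death probabilities
computed analytically along each path. The reported truth is
`Σ e(1−e)(r₁−r₀) / Σ e(1−e)` with a Monte-Carlo SE from the weighted-ratio
variance. Under a homogeneous or null effect this coincides with the
covariate-level overlap estimand the analysis targets; under heterogeneous
effects the two conditioning levels can differ slightly (documented, not
hidden).

## What a green test establishes — and what it does not

The generator reproduces confounding by indication, terminal attrition,
drug mix, dose tiers and MAR lab missingness. It does **not** emulate
informative censoring, competing risks, practice drift, measurement error
in treatment records, unmeasured confounding (e.g. clinician "salvage"
intent), or the real ~280-covariate DAG (covariate lists are configurable;
~40 engineered columns stand in). Oracle-recovery and coverage results on
synthetic data therefore validate the estimator machinery, not the clinical
conclusions of any real-data analysis.

## Numerical conventions

Probability clip 1e-6; exponentiated-gradient tolerance 1e-8; simplex ties
to the first-listed learner; sample variance with n−1; percentage tables
rounded to 1 decimal; all RNG through `numpy` `SeedSequence` spawning, so
every artifact is reproducible from a single integer seed.

## Known limitations

* Influence-function SEs ignore imputation-model and ensemble-weight
  uncertainty (standard practice; the bootstrap option partially covers it).
* Window estimates share patients and a terminal outcome, so the 13-cell
  series is correlated; no joint inference across windows is attempted and
  no multiplicity correction is applied (the series is descriptive).
* Late, high-dose cells on small cohorts rest on effective sample sizes in
  the tens; with an unpenalised GLM and ~40 covariates the propensity can
  saturate there — use the penalized learner (or the full ensemble) for
  small cohorts, as `scripts/acceptance.py` does.
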
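# Methods

## Problem and data model

The package classifies subjects into PTSD (group 1) versus trauma-exposed
control (group 2) from a stacked table of subject-day mobility summaries:
daily minutes away from home (DMA, minutes in [0, 1440], "away" meaning
beyond a 500 m radius around the home geocode) and maximum daily radius
(MDR, km ≥ 0), over 3–7 observed days per subject. The positive class is
group 1 throughout, and a subject is classified positive when its predicted
probability strictly exceeds the operating threshold.

## Trace reduction

When raw coordinate traces are available they are reduced per day by
`ptsdgps.geo`:

* **Distance.** Equirectangular planar distance: latitude and longitude
  degree differences are converted to km separately (111.32 km/degree,
  longitude scaled by cos of the mean latitude of the pair) and combined by
  the Pythagorean theorem. Against a spherical haversine reference the
  relative error is below 1% for pairs within 50 km below 70° latitude
  (property-tested); geodesic corrections would be noise at these scales.
* **Away classification.** Strictly greater than the home radius counts as
  away; a point at exactly 500 m is at home. Some convention is required at
  the boundary and the at-home reading is conservative.
* **Time attribution.** Each GPS fix represents the interval until the next
  fix; the last fix of a day carries the day's median interval, and a
  single-fix day falls back to a configurable default (1 minute). Interval
  weighting keeps DMA meaningful under irregular sampling.
* **MDR** is the maximum distance from home over *all* fixes, including
  those inside the home radius — it is a radius around home, not a radius
  while away.
* No GPS noise filtering or stay-point clustering is applied.

## Synthetic cohorts

`ptsdgps.synthetic` generates cohorts with the structure the pipeline is
designed to detect. Per subject *i*, group *g*, day *d*:

* DMA_id = clamp( μ_DMA + β_DMA·[g = 2] + b_i + ε_id , 0, 1440 ), with
  b_i ~ N(0, σ_subj²), ε_id ~ N(0, σ_noise²);
* log MDR_id = μ_logMDR + β_MDR·[g = 2] + γ_weekend·[weekend] + b'_i + ε'_id,
  so radii are log-normal (nonnegative, right-skewed).

Defaults (the "study-like" preset): 150 group-1 and 35 group-2 subjects;
3–7 days kept per subject by uniform day dropout from a 7-day week (Monday
start, days 6–7 weekend); μ_DMA = 240 min, β_DMA = −85 min with
σ_subj = σ_noise = 60 min (a ≈ 1-SD standardized shift of the subject
means — controls spend less time away); μ_logMDR = 1.0 log-km
(median ≈ 2.7 km), β_MDR = −0.5 with σ'_subj = σ'_noise = 0.35
(≈ 1 SD), γ_weekend = −0.3 log-km (everyone travels less far on weekends).
Only the direction of these effects and the cohort geometry come from the
study design; the absolute values are conventions chosen once for a
realistic, clearly detectable signal. A "null" preset zeroes both group
effects for calibration checks. Generation is a pure function of the
configuration (bit-reproducible given the seed).

What the generator does *not* emulate: clinical covariates and comorbidity,
realistic urban mobility (road networks, multi-modal travel), day-to-day
autocorrelation beyond the subject intercept, missingness that is informative
about diagnosis, and GPS measurement error. Passing pipeline tests on these
cohorts therefore demonstrates that the machinery recovers the planted
group/weekend/subject structure at the study's scale and imbalance — not
that real PTSD cohorts carry that much signal.

`generate_gps_trace` builds one-day coordinate traces whose true minutes
away and maximum radius are known by construction, to round-trip the trace
reduction.

## Feature engineering

* The 15 distributional statistics use the n−1 sample variance, OLS slope on
  day index, RMSSD = sqrt(mean squared successive difference), and linearly
  interpolated ("type 7") quantiles — the defaults of mainstream statistical
  environments. Single-day subjects get variance/slope/RMSSD of 0 rather
  than missing, keeping the matrix complete.
* Random intercepts are REML BLUPs from the intercept-only one-way mixed
  model y_ij = μ + b_i + ε_ij, fitted with statsmodels MixedLM and verified
  against the closed-form balanced-design shrinkage
  n τ²/(n τ² + σ²)(ȳ_i − μ̂); a singular fit falls back to centered subject
  means with a warning. Intercepts are estimated once on the full stacked
  table, as a feature-construction step.
* Weekend features for subjects with no weekend (or no weekday) days, the
  weekday/weekend MDR ratio with a zero weekend mean, and the weekend-away
  percent with zero total DMA are left missing and resolved by training-fold
  mean imputation — the only imputation rule in the design, and one that
  avoids manufactured infinities.
* Standardization maps constant training columns to 0 instead of dividing
  by zero. Both imputation means and scaling statistics are learned on the
  training partition of each fold only. Whether the original analysis
  preprocessed per fold or globally is not documented; the leakage-safe
  per-fold reading is used, which can cost a little apparent performance but
  makes the out-of-fold claim exact.

## Learners and resampling

Five families: XGBoost with the DART booster (dropout of boosted trees;
40 rounds, depth 2–3, learning rate 0.3, rate_drop tuned), a PLS discriminant
(±1-coded target, 1–5 components, logistic calibration of the latent score),
lasso-regularized logistic regression (liblinear, C tuned), an RBF SVM with
Platt-scaled decision scores, and a random forest standing in for the
conditional-inference forest family (no permutation-test forest exists in
this ecosystem; the substitution is flagged `rf_fallback` in provenance and
matters little here because forests enter as one of five stacked learners).

SMOTE is implemented directly from its definition: each synthetic minority
row is x_i + u (x_nn − x_i), u ~ U(0,1), with x_nn one of the k = 5 (auto-
reduced) nearest minority neighbours post-standardization; the target is
full class balance. It is applied inside every training split, never to
held-out data.

Resampling engines:

* **Nested LOSO** (arm 1): one day-level model per held-out subject, tuned
  by subject-grouped 5-fold inner CV on the remaining subjects. A second
  LOSO inner loop would multiply cost ~40-fold for no qualitative change.
* **Repeated stratified k-fold** (arms 1–3 second stage and the ensemble):
  10 folds × 5 repeats, stratified by class so the 35-subject minority never
  empties a fold; per-subject probabilities are averaged over repeats to one
  value per subject per model. Fold assignment is a deterministic function
  of (seed, repeat, subject ids, labels). Because stratification consults
  labels, the label-flip leakage audit is exact for LOSO, while for k-fold
  the audit establishes that a held-out subject's features never reach its
  own model (co-fold perturbation test); its label can still move fold
  boundaries, which is a property of stratification, not leakage into
  training.
* Grid tuning scores every grid point by inner-CV ROC-AUC (3-fold in the
  k-fold stages) and refits the winner; single-point grids skip the inner
  loop. Default grids hold 2–3 points per family; `PipelineConfig.fast_config`
  uses single-point grids so a full 185-subject, three-arm run takes about a
  minute on one CPU — the problem size used by the test suite and the
  acceptance script (five such runs).

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), computed with
sklearn and cross-checked in tests against brute-force pair counting. The
"balanced" sensitivity/specificity pair sits at the threshold maximizing
Youden's J = sens + spec − 1, ties broken toward the smallest
|sens − spec|; balanced accuracy is their mean. Raw accuracy and Cohen's κ
are reported at the fixed 0.5 threshold — the customary default — while the
balanced metrics use the ROC-optimal threshold; both thresholds are recorded
in the report, since with an 81% majority class the two conventions can
diverge noticeably. κ with degenerate marginals (p_e = 1) is defined as 0.

## Known limitations

* The conditional-inference forest is approximated by a standard random
  forest (flagged in provenance).
* Default and fast tuning grids are deliberately small; serious
  hyperparameter searches should supply larger grids through
  `PipelineConfig.grids` and expect proportional runtime.
* The synthetic generator's effect sizes are conventions; absolute
  performance numbers on synthetic cohorts characterize the pipeline, not
  any clinical population.
* No confidence intervals on AUC, no model introspection / variable
  importance, and no home-location inference (the home geocode is an input).
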
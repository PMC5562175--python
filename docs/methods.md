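# Methods

## The model

The package's central object is a linear model for the square root of the
glomerular filtration rate:

```
√GFR = β₀ + β₁·Age + β₂·BSA + β₃·L + β₄·L² + β₅·L³
       + (β₆ + β₇·Age)·[Sex = M] + β₈·Age·BSA + ε,   L = ln(Cre),  ε ~ N(0, σ²)
```

with Age in years, BSA the Du Bois body surface area in m²
(0.007184·height^0.725·weight^0.425), and Cre the serum creatinine in mg/dL
(records carried in µmol/L are converted at the single design-construction
point; 1 mg/dL = 88.42 µmol/L).

The square-root response scale is not an aesthetic choice: on oncology
cohorts the raw GFR distribution is right-skewed and heteroscedastic, while
√GFR is approximately normal with constant residual variance, which is what
makes the classical linear-model predictive machinery applicable.  The
package's Box-Cox module makes this reproducible: the profile log-likelihood
ℓ(λ) = −(n/2)·ln(RSS_λ/n) + (λ−1)·Σln y over the power family is maximized
near λ = 0.5 whenever the generative truth lives on the √ scale.

The cubic polynomial in ln(Cre) captures the curvature of the
GFR–creatinine relationship that a single log term misses; the sex offset
with a sex-by-age interaction and an age-by-BSA interaction let the age
slope differ by sex and body size.

### Prediction, intervals, threshold probabilities

For a new covariate row x, ordinary least squares gives the √-scale
prediction βᵀx with predictive variance σ̂²(1 + xᵀ(XᵀX)⁻¹x).  The package
reports:

* **point estimate** (max(0, βᵀx))² in mL/min — the square of the √-scale
  mean, with no retransformation correction, since the predictive
  distribution is symmetric on the modeled scale and the squared-mean
  estimate is the convention for this model family.  An optional
  bias-corrected estimate ŷ² + σ̂²(1 + h) is available behind a flag;
* **predictive interval** βᵀx ± t_{n−p,(1+γ)/2}·√(σ̂²(1+h)), endpoints
  clamped at zero on the √ scale and squared.  t rather than normal
  quantiles because σ is estimated; at n ≈ 2,000 the difference is
  negligible but the t form is exact under the model;
* **threshold probability** P(GFR < c) = F_t((√c − βᵀx)/√(σ̂²(1+h))), the
  quantity a clinician needs when a decision hinges on a cutoff such as
  50 mL/min for cisplatin.

Negative √-scale predictions (possible only for extreme covariates) are
clamped to zero and logged.  On the squared scale the model is therefore
non-increasing in creatinine everywhere and strictly decreasing wherever the
prediction is positive; the √-scale predictor is strictly decreasing in
creatinine across the whole 0.2–10 mg/dL calibration range (the cubic's
derivative has negative discriminant for the packaged coefficients, so there
is no interior sign change).

A model object restored from coefficients alone (no σ², n, or cross-product
inverse) supports point prediction only and raises a capability error on
interval requests rather than fabricating uncertainty.

## Model development machinery

Term selection is a greedy forward search from the intercept-only model over
a candidate pool {Age, BSA, Height, Weight, Sex, ln(Cre), ln(Cre)²,
ln(Cre)³, Sex×Age, Age×BSA} (configurable).  A polynomial or interaction
term is admissible only when its lower-order parents are already present.
Three criteria are implemented, all scored on the √ scale:

* **BIC** n·ln(RSS/n) + p·ln(n), with constant terms dropped (scores are
  comparable only within one cohort);
* **leave-one-out CV** via the PRESS leverage shortcut Σ(eᵢ/(1−hᵢᵢ))²/n,
  algebraically identical to explicit delete-one refitting;
* **five-fold CV** with a seeded random partition.

Ties break toward the earliest pool term; the search stops when no addition
strictly improves the criterion.  Because the k-fold criterion carries
partition randomness, selection is repeated over deterministically derived
child seeds and the modal model is taken forward, with the full frequency
table reported.

Forward-only search is the default; a deletion pass is deliberately not
implemented because the hierarchy constraint plus forward search already
reproduces the intended behavior and keeps the repeated-selection loop cheap.

The null-model consistency property — on data with no covariate signal the
search should return the intercept-only model — holds for BIC (whose
penalty grows with n) and is checked at the ≥90/100-replicates level for it.
The cross-validation criteria are not selection-consistent: each pure-noise
candidate is admitted with probability ≈ P(χ²₁ > 2) ≈ 0.16, so with a
10-term pool the null model is returned in only ~17% of runs no matter the
sample size.  This is a known property of CV-based selection, not an
implementation defect, and is why the strict null-recovery check is tied to
BIC while the modal-model recovery check under a true signal is applied to
all three criteria.

Diagnostics: Cook's distance Dᵢ = eᵢ²hᵢᵢ/(p·σ̂²·(1−hᵢᵢ)²) (identical to the
delete-one definition), and a Breusch-Pagan auxiliary regression of squared
residuals on the design as the heteroscedasticity check backing the
constant-σ² interval machinery.  The Breusch-Pagan choice is this package's;
graphical residual assessment is the usual alternative.

## Comparator equations

The seven published equations are transcribed from their primary references
into a single constants table (`camgfr/constants.py`) with the creatinine
unit and native output scale declared per formula: Cockcroft-Gault (1976)
and Jelliffe (1973) estimate creatinine clearance, Wright (2001) and Martin
(1998) absolute GFR, and the Mayo quadratic (2004, with its 0.8 mg/dL
creatinine floor), IDMS MDRD (175 coefficient) and CKD-EPI (2009) normalized
GFR in mL/min/1.73 m².  Normalized outputs are converted to absolute mL/min
by value × BSA/1.73.  The Jelliffe 1973 and the Martin forms are the
variants wired in; both are registry entries and swappable.  MDRD/CKD-EPI
race factors are implemented but default to the non-black factor, matching
the white-only population the model targets; they are explicit inputs.

A frozen 65-case fixture panel (5 patients × all formulas, BSA values and a
Calvert dose), computed by a separate straight-line arithmetic script before
the registry was written, guards every coefficient at 0.1 mL/min.

## Evaluation framework

Sign conventions, stated once and used everywhere: residual = measured −
estimated (positive median residual = underestimation); PE = 100·(estimated
− measured)/measured, so a model that overestimates has positive PE.  RMSE
carries a χ²-pivot CI (n·RMSE²/σ² ~ χ²ₙ for mean-zero normal errors).
Carboplatin dose errors are computed on Calvert doses, AUC·(GFR + 25) — the
+25 offset makes the dose APE systematically smaller than the GFR APE and
the target AUC cancels in the APE.  Thresholds are strict: dose APE "> 20%"
and GFR "< 50 mL/min" do not count boundary-equal cases.  Bland-Altman
limits are mean ± 1.96·SD of the differences; box-plot notch half-widths are
1.58·IQR/√n when plot data are exported.  `compare_models` orders its report
by ascending RMSE and reports per-model failures in-row.

## Synthetic cohorts

No patient-level data ship with the package, so a generator provides cohorts
whose structure matches the modeling assumptions: per-sex covariate
distributions (age truncated-normal(62, 12) on [18, 95]; height normal
176/163 ± 7 cm; weight truncated-normal 80/70 ± 15 kg, min 35; creatinine
log-normal per sex with σ_log = 0.45) and measured GFR generated as
(max(0, βᵀx + ε))² with ε ~ N(0, σ_sqrt²), σ_sqrt = 0.83.  At √GFR ≈ 9 the
delta method gives a GFR-scale error of ≈ 2·√GFR·σ_sqrt ≈ 15 mL/min, placing
synthetic experiments in the accuracy regime reported for creatinine-based
estimation in cancer cohorts.  The creatinine-to-isotope-study interval is
log-normal with median ≈ 6 days, truncated at the 30-day admission window.

The default ground-truth coefficient vector is a synthetic stand-in on the
model's functional form, not a transcription of any fitted clinical model.
It was calibrated once, jointly, to three requirements and then frozen:

1. the development cohort reproduces the published summaries a mixed-sex
   oncology cohort shows (median measured GFR ≈ 81 mL/min inside the 63–103
   IQR; the external all-male seminoma configuration median ≈ 113 mL/min at
   median age 39);
2. physiological sanity: √GFR strictly decreasing in creatinine over the
   clinical range, GFR declining with age (≈ 1 mL/min/year net, carried
   jointly by the main effect and the Age×BSA and Sex×Age interactions),
   larger body size → higher absolute GFR;
3. identifiability: every generative term carries enough partial signal at
   the n ≈ 2,000 development scale (|t| ≳ 4) that term selection is a
   well-posed recovery problem rather than a coin flip.  This constrains the
   creatinine log-spread (0.45) and the interaction magnitudes.

What the generator does **not** emulate: the empirical joint distribution of
any real cohort (covariances between body size, age and creatinine are
simplified), assay error in creatinine, within-patient repeat measurements,
or model misspecification — the generative truth *is* the fitted model
family.  Passing tests therefore demonstrate that the machinery is correct
and calibrated under its own assumptions (intervals cover at the nominal
rate, selection recovers the truth, the correctly specified model out-ranks
the comparator equations), not that the packaged default coefficients are
clinically accurate for real patients.

## Numerical choices

* OLS via pivoted QR; (XᵀX)⁻¹ reconstructed from R⁻¹ for the leverage and
  interval machinery; rank deficiency raises an error naming the collinear
  terms (tolerance: max|diag R| · max(n,p) · ε).
* Box-Cox grid: λ ∈ [−1, 2] in steps of 0.02 by default.
* Random-split sizes round half away from zero (2,471 × 0.8 → 1,977
  development / 494 validation records exactly); splits preserve input
  record order within each part.
* Seed fan-out for repeated selection uses `numpy` seed sequences on
  (master, repetition) pairs; every derived seed is reported.
* Cohort CSV floats are written with `repr` so write/read round-trips are
  bit-for-bit.
* The admission filters (age ≥ 18, creatinine within 30 days of the GFR
  measurement) reject records into an explicit issue report rather than
  failing the read, so partial cohorts stay usable.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use development cohorts of
n = 1,977–2,471, validation cohorts of n = 494, an external cohort of
n = 111, interval-calibration checks on 10,000 fresh patients with 10⁵
Monte-Carlo draws, and 100-replicate selection/ranking studies with
50-repetition modal selection in the acceptance script — the repetition
counts are scaled-down analogues of the multi-thousand-repetition studies
this kind of development pipeline uses at full scale, chosen so the whole
suite runs in a few minutes on one core.

## Known limitations

* The packaged default coefficients are synthetic (see above); for clinical
  use the model must be refit on real cohort data via `camgfr fit`.
* Race adjustment beyond the published MDRD/CKD-EPI factors, cystatin-C
  equations, and pediatric equations are out of scope.
* Backward/stepwise-with-deletion search is not implemented.
* The generator's covariate independence means comparator equations face a
  synthetic population that can differ from the populations they were
  developed in; their relative ranking on synthetic cohorts reflects the
  simulation's assumptions, not clinical performance.
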
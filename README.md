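# camgfr

Estimating the glomerular filtration rate (GFR) from routine blood work is a
daily task in oncology: carboplatin doses are computed directly from GFR via
the Calvert equation, dose [mg] = target AUC × (GFR + 25), and cisplatin is
used with caution below about 50 mL/min.  Gold-standard isotope-clearance
measurements (e.g. ⁵¹Cr-EDTA) are slow and expensive, so clinicians rely on
creatinine-based estimation equations — most of which were developed in
chronic-kidney-disease populations rather than in patients with cancer.

`camgfr` implements, for researchers and method developers:

* a **square-root-scale linear model for GFR** tailored to adult oncology
  cohorts, with per-patient **predictive intervals** and **threshold
  probabilities** P(GFR < c):

  ```
  √GFR = β₀ + β₁·Age + β₂·BSA + β₃·ln(Cre) + β₄·ln(Cre)² + β₅·ln(Cre)³
         + (β₆ + β₇·Age)·[Sex = M] + β₈·Age·BSA + ε,      ε ~ N(0, σ²)
  ```

  where BSA is the Du Bois body surface area and Cre the serum creatinine;
* the **seven published comparator equations** (Cockcroft-Gault, Jelliffe,
  Wright, Martin, Mayo quadratic, MDRD, CKD-EPI) behind one registry, with
  BSA adjustment for the normalized ones;
* the **model-development machinery**: Box-Cox response-transform selection,
  forward stepwise term search under BIC / leave-one-out CV / five-fold CV,
  repeated selection with a modal-model report, and regression diagnostics
  (Cook's distance, Breusch-Pagan);
* the **evaluation framework**: RMSE with a χ²-pivot CI, median residual /
  percentage error / absolute percentage error with IQRs, Bland-Altman
  limits, carboplatin dose-error fractions (APE > 20%), 2×2 threshold
  classification, and predictive-interval coverage;
* a **synthetic-cohort generator** calibrated to published oncology-cohort
  summaries, so the whole pipeline is exercisable without patient data.

## Worked example

Simulate a development cohort, fit the model on its 80% development split,
and estimate GFR for a single patient:

```sh
camgfr simulate --n 2471 --seed 1 --out cohort.csv
camgfr fit --cohort cohort.csv --split-ratio 0.8 --seed 1 --out model.json
camgfr estimate --model model.json \
    --age 64 --sex F --height 162 --weight 66 --creatinine 88 --unit umol/L
```

prints

```
eGFR 62.7 mL/min [95% PI 40.2-90.2], P(GFR<50) = 0.147; BSA-adj CKD-EPI 58.9 mL/min
```

i.e. for this 64-year-old woman with creatinine 88 µmol/L the point estimate
is 62.7 mL/min, the true GFR lies in 40–90 mL/min with 95% probability, and
there is a 15% chance it is below the 50 mL/min cisplatin-caution value; the
BSA-adjusted CKD-EPI estimate is shown alongside for comparison.

Comparing all models on a fresh simulated validation cohort:

```sh
camgfr simulate --n 494 --seed 2 --out val.csv
camgfr evaluate --cohort val.csv --model model.json
```

```
n = 494; residual = measured - estimated
model                     RMSE  CI low  CI high  med.resid  med.PE%  med.APE%  doseAPE>20%
New model                16.52   15.56    17.62       1.63    -2.35     13.51        17.00
BSA-adj Jelliffe         21.15   19.91    22.56       2.63    -3.51     15.84        27.73
Jelliffe                 21.77   20.50    23.22       7.18    -8.36     17.58        28.54
BSA-adj CKD-EPI          22.37   21.06    23.86      -1.02     1.42     17.26        30.97
...
new-model 95% predictive intervals: coverage 93.3%, 38.1% contain 50 mL/min
```

Rows are ordered by ascending RMSE (mL/min).  The refit square-root model
has the lowest RMSE and the smallest fraction of carboplatin doses more than
20% off the dose implied by the simulated measured GFR; its 95% predictive
intervals cover about 95% of measured values.

`camgfr select` runs the stepwise search (`--criterion bic|loocv|kfold`,
`--reps` for the modal-model repetition) and reports the Box-Cox λ, which is
≈ 0.5 on cohorts whose truth lives on the square-root scale.

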
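# fragscore

Mortality risk scores and external-validation statistics for elderly
fragility hip fracture cohorts.

Elderly patients who fracture a hip after low-energy trauma face one-year
mortality rates of 16–33%, yet no consensus exists on which of the many
published prognostic scores to use at admission. `fragscore` implements
seven widely cited hip-fracture mortality scores — the Sernbo score, the
Jiang et al. comorbidity model, the Nottingham Hip Fracture Score (NHFS),
the Holt et al. linear predictor, HEMA (Hip fracture Estimator of Mortality
Amsterdam), the ASAgeCoGeCC score, and SHiPS (Shizuoka Hip Fracture
Prognostic Score) — together with the full external-validation toolkit used
to compare them, and a seeded synthetic cohort generator so every stage of
the pipeline can be exercised without patient data.

It is written for clinical epidemiologists and biostatisticians validating
prognostic models on their own hip-fracture cohorts.

## What it computes

**Risk scores.** Each model is a weighted sum over binned covariates,
S = Σᵢ wᵢ(xᵢ), with published cutoffs partitioning S into ordered risk
strata. Two models carry probability transforms:

- NHFS: predicted 30-day mortality (%) = 100 / (1 + e^(5.0122 − 0.481·S))
- Holt: predicted mortality = 1 / (1 + e^−(c + Σ βᵢ)), where the constant
  c was never published; `derive_holt_intercept()` back-solves c ≈ −4.79
  from the published stratum-boundary pair (Σβ = 2 → 5.8%, 4.92 → 53.2%).

All weight tables, transforms, and stratum cutoffs live in an editable
packaged YAML config, validated at load time by brute-force enumeration of
each model's attainable score set.

**Validation statistics**, implemented from first principles:

- ROC AUC via the Mann–Whitney rank statistic (ties ½) with DeLong
  placement-value confidence intervals, and the paired DeLong test for
  comparing correlated AUCs;
- Hosmer–Lemeshow goodness-of-fit on quantile bins of predicted risk with
  explicit tie handling, and the calibration slope/intercept (logistic
  regression of outcome on logit(p), safeguarded Newton–Raphson);
- sensitivity/specificity/PPV/NPV at an explicit or Youden-optimal cutoff;
- risk-stratum tables with the symmetric accuracy statistic
  100·min(p,o)/max(p,o) comparing predicted and observed mortality;
- the Hanley & McNeil minimum sample size for a target AUC CI half-width;
- Kaplan–Meier curves and the two-group log-rank test (via `lifelines`).

## Worked example

```python
from fragscore import load_model_config, score_patient, nhfs_probability
from fragscore.cohort_io import Sex
# ... build a PatientRecord p: age 83, female, Hb 11 g/dL, 3 comorbidities,
# living at home, alert, no malignancy ...
panel = score_patient(p, load_model_config()["nhfs"])
print(panel.raw_score, panel.stratum)      # 4 intermediate
print(round(nhfs_probability(4), 1))       # 4.4
```

The patient scores 3 points for age 66–85 and 1 for having two or more
comorbidities; a total of 4 places her in the intermediate-risk stratum
with a predicted 30-day mortality of 4.4%.

A full study-style run on a simulated cohort of 207 patients:

```bash
fragscore run --n 207 --seed 1 --out-dir out/
```

writes per-patient score panels, per-model validation reports, the 7×7
DeLong p-value matrix, discrimination/calibration and risk-stratification
tables, and a Kaplan–Meier curve. The discrimination table from that run:

```
model        auc_95ci          auc_oriented_95ci  hl_p  calibration_slope_95ci
sernbo       0.26 (0.19-0.33)  0.74 (0.67-0.81)   NA    NA
jiang        0.83 (0.77-0.89)  0.83 (0.77-0.89)   0.00  1.80 (1.09-2.50)
nhfs         0.80 (0.74-0.86)  0.80 (0.74-0.86)   0.00  2.22 (1.41-3.02)
holt         0.87 (0.82-0.92)  0.87 (0.82-0.92)   0.00  2.22 (1.56-2.88)
hema         0.80 (0.73-0.86)  0.80 (0.73-0.86)   0.00  0.27 (0.17-0.38)
asagecogecc  0.78 (0.72-0.85)  0.78 (0.72-0.85)   0.00  0.42 (0.26-0.58)
ships        0.81 (0.74-0.87)  0.81 (0.74-0.87)   0.00  1.21 (0.81-1.60)
```

The Sernbo score increases with expected *survival*, so its as-published
AUC sits below 0.5 while the orientation-corrected column shows its true
discrimination; all seven models discriminate well on the synthetic cohort
because its outcome model loads on the same covariates the scores use.
The low calibration p-values are expected: the scores' 30-day probability
scales are being confronted with one-year outcomes.

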
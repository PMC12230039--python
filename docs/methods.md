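# Methods

## Scope and data model

`fragscore` targets the external-validation workflow for prognostic models
in elderly surgical fragility hip fracture populations: patients aged 60+
with osteoporosis (DXA T-score ≤ −2.5), surgically treated, excluding
pathological and periprosthetic fractures, with the binary endpoint
*death within 12.0 months of surgery* (boundary inclusive) plus follow-up
time in months for survival analysis. A `PatientRecord` carries the union
of covariates the seven scores require; `dead_1y` is missing exactly when
a patient is lost to follow-up, and such patients are excluded by the
default eligibility filter. When a patient has two admissions (bilateral
fractures), the earliest admission is kept.

## Score configuration

Every weight table, probability transform, and stratum cutoff is data, not
code (`data/default_models.yaml`). The scoring engine understands four
component kinds (numeric bands, categorical maps, boolean flags, numeric
thresholds); a model's attainable score set is enumerated by taking the
Cartesian product of per-component weight options, and the config loader
rejects any config whose strata overlap or fail to cover an attainable
score. Holt and HEMA carry fractional weights (e.g. 1.74, half points), so
scores accumulate as exact decimals — stratum boundary comparisons such as
"score ≤ 2" must never depend on binary float representation.

Three source-table cells required judgement:

- the ASAgeCoGeCC CCI row is corrupted in the source; the default config
  uses 3 points for CCI 3–4 and 7 for CCI > 4, marked unverified against
  the score's original publication and correctable in the YAML;
- the NHFS low-risk predicted bound is corrupted; 2.7% is what the NHFS
  transform yields at the stratum cutoff (score 3), and this
  reconstruction is confirmed by the published low-risk accuracy cell;
- the HEMA low-risk predicted bound is corrupted; 5.6% back-solves from
  the published accuracy (45.9 with observed 12.2%) under the accuracy
  statistic and is consistent with a single-digit corruption.

Two further published inconsistencies are configured around rather than
resolved: the Sernbo total "13" is unattainable from four {2, 5} items
(14 is used, matching the printed moderate-risk cutoff), and the SHiPS
printed maximum of 64 exceeds the brute-force maximum (60) of its printed
weights (the stratum upper bound is kept at 64).

The Sernbo score is the only model oriented so that *higher = better
survival*; its config carries `orientation: -1`. Validation reports both
the as-published AUC and the orientation-corrected AUC, and thresholds are
searched on oriented scores.

The NHFS cognition item here is a *history of cognitive impairment* rather
than an Abbreviated Mental Test Score below 7 — the standard retrospective
adaptation — and reports record this substitution. "Living in an
institution" maps to long-term care, rehabilitation, or admission from an
acute ward; sheltered/assisted housing counts as home.

## Probability sources

NHFS probabilities come from its published logistic transform. The Holt
transform's constant was never published: it ships unset, the transform
raises an explicit "unconfigured" error rather than defaulting, and
`derive_holt_intercept()` documents the inversion of the published
stratum-boundary pair (linear predictor 2 → 5.8%, 4.92 → 53.2%) giving
c ≈ −4.79, a 30-day constant. The pipeline applies it by default so that
calibration statistics exist for Holt. The remaining models publish no
usable formula; their predicted probability defaults to the stratum-level
predicted mortality (piecewise-constant), which is what feeds the
Hosmer–Lemeshow and calibration-slope computations for them. Interval
predicted mortalities are summarized by the interval's upper bound by
default (`interval_mode="lower"` switches); the source tables themselves
mix both conventions across rows.

## Validation statistics

**AUC / DeLong.** AUC is the Mann–Whitney statistic with ties counted ½,
identical to exhaustive concordant-pair counting (asserted against that
oracle in tests). Variance and the paired test use DeLong placement
values; confidence intervals are normal-approximation, truncated to
[0, 1]. Degenerate comparisons (identical scores) return z = 0, p = 1.

**Hosmer–Lemeshow.** Patients are binned into quantiles of predicted risk.
Piecewise-constant predictions create heavy ties, so when there are no
more distinct predicted values than requested groups, each distinct value
forms its own bin; bins with zero expected deaths or survivors are
collapsed into a neighbor. The statistic is Σ(O−E)²/E over deaths and
survivors. Degrees of freedom default to the number of effective bins
(`df_style="validation"`): when probabilities were not fitted to the data
at hand, each bin contributes an (approximately) full χ²₁ term, and
simulation confirms the nominal 5% type-I error only under this choice.
The classic g − 2 rule, appropriate for development data, is available as
`df_style="development"`.

**Calibration slope.** Logistic regression of the outcome on
logit(clipped p), fit by Newton–Raphson with step-halving on the
log-likelihood (plain Newton can diverge from a distant start), tolerance
1e−8, 50 iterations max; Wald 95% intervals from the inverse observed
information. Constant predictions are flagged degenerate; separation and
non-convergence are flagged, never raised.

**Classification.** The source study does not state how its operating
points were chosen; the default threshold is Youden-optimal
(max sens + spec − 1) over observed score values, ties broken toward
higher specificity, with the threshold recorded in the report.

**Stratum accuracy.** The agreement statistic between predicted and
observed stratum mortality is the symmetric ratio 100·min(p, o)/max(p, o),
which reproduces every published point-prediction accuracy cell; 100 when
both are zero, 0 when exactly one is zero.

**Sample size.** `hanley_mcneil_n` inverts the Hanley & McNeil SE formula
(Q₁ = A/(2−A), Q₂ = 2A²/(1+A)) by binary search for the smallest total N,
splitting N into events and non-events by a prevalence parameter; all
assumptions (AUC, CI half-width, prevalence, z) are explicit arguments.

**Survival.** Kaplan–Meier and the log-rank test wrap `lifelines`; ties at
a time process deaths before censorings. Because the record schema stores
only one-year vital status, deaths after 12 months are indistinguishable
from censoring and are treated as censored at the end of follow-up.

**Multiplicity.** The 21 pairwise DeLong p-values are reported raw, as is
conventional in single-study model comparisons; no adjustment is applied
by default.

## Synthetic cohort generator

The generator emulates the marginal profile of a single-center elderly
Chinese surgical cohort: median age 83 (the printed spread 71–95 is read
as the IQR by default; a narrower "range" preset exists because such a
wide IQR may be a range), 77.8% female, 97.1% with ≥ 2 comorbidities,
46.9% ASA > 2, 2.4% cognitive impairment, 7.2% institutional residence,
23.2% dependent mobility, and a 29.0% one-year mortality target.

Dependence is induced by a single latent standard-normal frailty per
patient rather than a full copula: each binary covariate is a thresholded
Gaussian loading on the frailty (loading 0.45 by default), ordinal
covariates (ASA, residence, mobility, malignancy) use ordered thresholds
on the same latent, age couples with loading 0.35, and labs shift with
frailty (hemoglobin down, urea up). This is the minimal mechanism that
makes every score discriminate and populates the high-risk strata.
Comorbidity-flag prevalences are configurable; defaults are typical for
geriatric hip-fracture series (e.g. CHF 11%, renal disease 12%,
any malignancy 11.5%).

Outcomes follow a logistic model on within-sample-standardized covariates
with default coefficients between 0.2 and 0.9 log-odds per SD (age 0.9,
male 0.8, frailty 0.6 the largest); the intercept is solved by root
finding so the cohort-average event probability equals the target
mortality exactly in expectation. Event times are Weibull with shape 0.65
(hazard concentrated in the first postoperative year), per-patient scale
set so P(T ≤ 12 months) equals the patient's modeled probability;
censoring is administrative, uniform between 12 and 62 months (uniform
accrual, maximum follow-up 62 months, everyone observable for the one-year
endpoint). Optional fractions of non-surgical, pathological-fracture,
osteoporosis-negative, and lost-to-follow-up records exist to exercise the
eligibility filter and default to zero.

What passing tests on this cohort do **not** show: the generator matches
stated marginals and a one-factor dependence structure only, so absolute
AUCs, calibration slopes, and H-L p-values on synthetic data are
properties of the generator, not estimates of any real cohort's values;
the study's patient-level results are not reproducible without its data.
Deliberately, all seven scores share covariates with the outcome model, so
synthetic discrimination is uniformly good — the pipeline's qualitative
pattern (all oriented AUCs > 0.5, Sernbo as published < 0.5, 30-day
probability scales miscalibrated against one-year outcomes) mirrors the
study; the numbers do not.

## Problem sizes and numerical choices

Statistical property tests use: H–L type-I error over 500 replicates at
n = 2000; calibration-slope CI coverage over 200 replicates at n = 5000;
log-rank type-I error over 500 replicates at 500 per arm; the DeLong
p-value checked against a 20,000-replicate paired bootstrap at n = 40;
discrimination-pattern checks at n = 2000. These sizes give Monte Carlo
error comfortably inside the asserted bands while keeping the default
suite under a minute of simulation time.

Probabilities are clipped to [1e−6, 1 − 1e−6] before logits; stratum
bounds and scores compare as exact decimals; the Youden search is
deterministic with an explicit tie-break; all random draws flow from
`numpy.random.default_rng(seed)` so cohorts and pipeline bundles are
byte-reproducible given a seed.

## Known limitations

- The record schema's one-year endpoint truncates survival information
  beyond 12 months (see above); curves past the first year understate
  cumulative mortality.
- The ASAgeCoGeCC CCI weights are a flagged reconstruction pending
  verification against the score's original publication.
- HEMA's published 30-day probability formula is unavailable; its
  calibration statistics are computed from stratum-level probabilities and
  are correspondingly coarse.
- The generator makes no attempt to match joint distributions beyond the
  one-factor structure; do not use it to estimate real-world operating
  characteristics.
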
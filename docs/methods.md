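# Methods

## Scores and definitions

**IDAA1C** (insulin-dose-adjusted HbA1c) is `HbA1c(%) + 4 × DIR`, DIR in
U/kg/day; partial remission (PR) is IDAA1C ≤ 9, threshold inclusive.

**GTAA1C** (glycemic target-adjusted HbA1c) is `HbA1c(%) − 3 × f`, with
`f` the fraction of self-monitored capillary glucose readings inside
70–180 mg/dL; PR is GTAA1C ≤ 4.5, inclusive. `f` is a *fraction in
[0, 1]*, never a 0–100 percentage: only the fractional reading makes the
4.5 threshold coherent with clinical HbA1c values (7.5 − 3×1.0 = 4.5,
whereas a percentage would drive the score to −290). The implementation
rejects arguments above 1. Algebraic consequences used as test
invariants: `HbA1c − 3 ≤ GTAA1C ≤ HbA1c` and `IDAA1C ≥ HbA1c`.

**BETA-2** is `√C-peptide[nmol/L] × (1 − DIR) / (glucose[mmol/L] ×
HbA1c[%]) × 1000`, an index of β-cell (graft) function computed from a
single blood sample. Values are reported exactly as the closed form gives
them — DIR > 1 U/kg/day produces negative scores, which are not clamped.
A `postprandial` flag records non-fasted sampling without changing the
arithmetic.

**DKA at diagnosis** is `pH < 7.3 and/or bicarbonate < 16 mM`, both
comparisons strict. **Age groups** at diagnosis are [0, 5), [5, 10) and
[10, ∞) years; the boundary ages 5 and 10 belong to the older group.

## Glycemic-variability summaries

Per-visit summaries are computed on the readings attributed to the visit:
count, mean, standard deviation, CV = SD/mean, and fraction in range.

- The normoglycemic interval is **closed at both ends** (70 and 180 mg/dL
  count as in range) — the conservative clinical reading of the target
  band.
- SD uses the **population denominator n**. These are descriptive
  summaries of the readings actually reviewed at a consultation, not
  estimates of a sampling distribution; the choice is tested explicitly.
- mmol/L values are converted with 18.016 mg/dL per mmol/L (glucose molar
  mass 180.16 g/mol).
- A summary is *sufficient* when it holds at least **5 readings**;
  GTAA1C is refused on insufficient summaries (the score would hinge on a
  couple of strips). Duplicate timestamps are kept as repeated
  measurements.
- **Visit-window attribution**: a reading belongs to the visit whose
  window it falls in, the window running from the previous visit date
  (exclusive) to the visit date (inclusive); readings after the last
  visit are dropped. Clinical practice does not fix a pooling window for
  "% normoglycemia at a visit"; since consultations are where logbooks
  are reviewed, the since-last-visit window is the natural unit. This is
  an implementation choice, and results at a visit change if a fixed
  trailing window is used instead.

## Episodes

A PR episode under a criterion is the **first maximal run of consecutive
qualifying visits**: onset is the first qualifying visit's date, end the
last of that run, duration in months (days / 30.44). Interrupted
remissions produce re-entry runs, which `pr_episodes` lists, but only the
first run counts as "the" episode. A single-visit episode has duration 0
months; the alternative (extending to the next visit) injects schedule
artifacts into durations, so the deterministic convention was preferred.
Whether PR should require ≥ 2 consecutive qualifying visits is not
settled; single-visit episodes are allowed here and visible in the
episode table (`n_visits` column). For GTAA1C, visits without a
sufficient GV summary are removed from the sequence before runs are
delimited (they neither qualify nor interrupt); the per-cohort count of
such visits is reported.

## Cohort statistics

- **Contingency tests**: Pearson chi-square *without* Yates continuity
  correction when every expected cell count is ≥ 5, otherwise two-sided
  Fisher's exact. The correction-free variant is pinned by a published
  2×2 ((23,16),(68,20)) whose printed p = 0.035 is only reproduced
  without the correction (0.058 with it); the test suite enforces this.
- **Two-group comparisons**: Shapiro-Wilk at α = 0.05 on each group
  routes to the unpaired t-test (both normal) or Mann-Whitney; the route
  taken is returned with the p-value.
- **Diagnostic performance** is plain confusion-matrix sensitivity and
  specificity. The default evaluation unit in the pipeline is the
  patient-level "ever entered PR" label, the natural unit for a
  remission definition; per-visit scores remain available in the
  scorecard table for visit-level analyses. Degenerate references (all
  one class) are rejected naming the missing class.
- **Determinant modelling**: each covariate is screened in a univariate
  logistic regression (likelihood-ratio p; categorical covariates as
  whole indicator blocks, first sorted level as reference); covariates
  with p < 0.05 enter a multivariate maximum-likelihood logistic model
  reported as odds ratios with Wald 95% CIs. If nothing passes the
  screen, all covariates are entered so a model is always reported.
  Complete separation is reported (`converged=False` or an exploded CI)
  rather than raised.
- **GV variable selection**: OLS of a PR score on {HbA1c, fraction in
  range, mean glucose, SD, CV}, reporting natural and per-SD
  (standardized) coefficients with p-values. Exact collinearity (CV is
  SD/mean, and the generator couples mean glucose to HbA1c) is flagged
  via a rank check in `attrs["rank_deficient"]`, never silently dropped.
- **Band-duration analysis**: patients are binned by 3-month GTAA1C into
  (−∞, 3.5], (3.5, 4], (4, 4.5], (4.5, 5], (5, ∞), and the fraction
  whose PR duration exceeds 300 days is reported per band. Empty bands
  yield NaN (undefined), not 0. In the pipeline, patients with no
  episode contribute duration 0.

## The synthetic cohort generator

The generator emulates the statistical structure of a tertiary-center
new-onset series so every pipeline stage can be exercised end to end.
Defaults (all overridable in `SimulationConfig`):

- **Cohort composition**: 239 patients; age-group weights 39/88/112
  across <5 / 5–10 / ≥10 years; 53% boys; DKA probability 0.30
  (literature-typical onset rate; acid-base values are drawn consistent
  with the flag). Latent remitter status is logistic in DKA (OR 0.5) and
  mid-age (OR 2.0) with the intercept recalibrated by bisection so the
  marginal remitter fraction is exactly the configured 0.70.
- **Trajectories**: baseline HbA1c 10.8 ± 2.7% with age-group offsets
  (−1.1/−0.4/+0.6); visits at 15 days, 1 month, then every 3 months to
  36 months. HbA1c relaxes from baseline toward a plateau with time
  constant 1.5 months — 0.4 months once a remission episode starts,
  since the honeymoon *is* rapidly restored control. Remission plateau
  6.9 ± 0.30% (capped at 8.3), non-remission 7.8 ± 0.4% (floored at
  6.5); visit-level jitter 0.2% (≈ the analytic CV of the assay plus
  stable-phase variation; between-patient spread lives in the plateau
  terms). DIR is 0.28 ± 0.06 U/kg/day during remission and 0.85 ± 0.12
  (plus a slow secular rise) outside, so remitter IDAA1C dips below 9
  during the episode and non-remitters stay above it.
- **Episodes**: onset snapped to an early visit (0.5/1/3 months with
  probabilities 0.2/0.5/0.3, putting peak prevalence near 3 months);
  duration gamma with mean 8.9 and SD 8.6 months truncated to
  [1.8, 44.3] by rejection. `duration_coupling` makes longer episodes
  come with a lower remission HbA1c plateau (−0.35%/SD), lower DIR and
  lower within-window glucose CV, which is what makes the 3-month GTAA1C
  inversely predictive of duration.
- **Readings**: within each visit window the glucose mean follows the
  ADAG linear relation `mean(mg/dL) = 28.7 × HbA1c − 46.7` (external
  literature coefficients, configurable); values are lognormal
  (right-skewed, positive; a truncated normal is available behind
  `glucose_dist="truncnorm"`) with within-window CV 0.25 in remission
  and 0.33 outside — literature-informed, as the source series reports
  no SMBG variance. Five readings/day over a 14-day logbook window per
  visit (70 readings, giving the in-range fraction a sampling SD ≈
  0.06).
- **C-peptide** is simulated at the patient-year level only (assays at
  0/12/24 months), lognormal around remitter medians 0.21/0.22/0.11 and
  non-remitter 0.15/0.05/0.02 pmol/mL, scaled ×1.25 when the patient is
  still in episode at the assay (×0.75 after it has ended) and by
  exp(0.3·duration-SD) — residual β-cell function tracks the remission
  state, which is what makes BETA-2 correlate with both PR scores.
  Fasting glucose is drawn from the window mean with 12% lognormal
  noise.
- **Severe hypoglycemia** is a per-visit hazard matching 3-year
  cumulative risks of 23.5% (remitters) vs 34.8% (non-remitters).

All randomness flows through one `numpy` Generator seeded from the
config; identical configs give byte-identical tables.

What the generator does **not** emulate: real SMBG autocorrelation and
meal structure, HbA1c assay drift, non-adherent patients with missing
visits or empty windows, antibody dynamics, puberty-driven insulin
resistance beyond a linear DIR trend, and measurement of C-peptide under
standardized stimulation. Passing recovery tests therefore shows the
pipeline is correct and well-behaved under the assumed structure, not
that the scores would achieve the same operating characteristics in a
clinical series.

## Problem sizes and numerical conventions

Recovery properties are asserted on 1000-patient cohorts across 20 seeds
(prevalence within ±0.04 of the configured 0.70; GTAA1C-vs-IDAA1C
specificity ≥ 0.85 on average; pooled score r² ≥ 0.5 per seed; band
proportions non-increasing), sizes at which binomial noise is a few
tenths of a percent and each cohort simulates and evaluates in a few
seconds. The acceptance script uses eight 1000-patient cohorts. Oracle
equivalence (confusion counting, episode delimitation, in-range
counting, Fisher's exact vs hypergeometric enumeration) uses ≥ 1000
random small instances each. Months are converted at 30.44 days/month.
Ties at thresholds are inclusive everywhere (scores ≤ threshold, range
endpoints in range); the two-sided Fisher p-value follows the
point-probability ordering with a 1e-9 relative tie tolerance.

## Known limitations

- The published cohort is not available, so the headline clinical
  operating characteristics (72–73% sensitivity, 92% specificity,
  r² = 0.71 against IDAA1C, r² = 0.60 against BETA-2) cannot be
  recomputed; the synthetic mirrors reported by the acceptance script
  are qualitative analogues under the generator's assumptions.
- GTAA1C inherits the evaluation-unit ambiguity of "ever entered PR":
  with many visits, a patient-level label inflates both detection and
  false-positive chances relative to a per-visit analysis. Both views
  are exposed.
- The GV regression's predictor panel is intrinsically near-collinear
  (CV = SD/mean, mean tied to HbA1c); coefficients other than HbA1c and
  fraction-in-range should be read qualitatively, which is exactly the
  variable-selection narrative the regression supports.
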
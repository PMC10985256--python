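# Methods

`acticohort` analyses free-living wearable-accelerometer recordings from a
two-group, two-visit observational design: an ambulatory Friedreich-ataxia
(FRDA) cohort and age-matched controls wear a triaxial sensor at the waist
and at the non-dominant wrist for 7 consecutive days during waking hours, at
a baseline visit and again about one year later.  This note documents the
processing model, the statistical procedures, the synthetic-data model used
for end-to-end testing, and the numerical choices behind each.

## Epoch processing

The pipeline starts at epoch-level activity counts (the conversion of raw
30-Hz accelerations to counts, and the device vendor's step algorithm, are
upstream of this package; steps are consumed as an input column).  Counts
arrive per axis per epoch; sub-minute epochs are summed into the 60-s
analysis epoch, conserving totals exactly.  Counts per minute (CPM) on the
vertical axis (axis 1) drive intensity classification; the three-axis vector
magnitude (VM3) is the per-epoch Euclidean norm of the axis counts.

Timestamps are local wall clock with no time-zone arithmetic, and calendar
days run midnight to midnight, matching how wear diaries are kept.

## Non-wear detection

Non-wear is detected with the Choi count-based algorithm on the vertical
axis: a non-wear interval must span at least 90 min, consist of zero-count
epochs except for at most 2 min of non-zero "spikes", and each spike must be
flanked on both sides by at least 30 min of consecutive zeros.  The interval
boundary is inclusive (exactly 90 min of zeros is non-wear).  Runs are
evaluated over the whole recording and may span midnight; flags are cut into
calendar days only afterwards.  The 90/2/30 defaults are the published ones
for 60-s epochs; all three windows and the axis (vertical vs vector
magnitude) are configurable for sensitivity analysis.

The diary can only remove wear time: epochs outside the self-reported worn
intervals are forced to non-wear, epochs inside keep their algorithmic flag.
This makes the correction idempotent and monotone and avoids trusting
diaries to certify wear the counts do not support.

Days with less than 8 h of wear are dropped; a subject with no valid day is
excluded from the analysis set (with a logged warning rather than an error,
since this mirrors real attrition).

## The seven digital measures

All measures share one analysis mask — wear epochs on valid days — so a
measure can never mix denominators.  Intensity bins on vertical-axis CPM use
the Freedson adult cut-points: sedentary <= 99, light 100-1951, moderate
1952-5724, vigorous >= 5725 CPM.  The same cut-points are applied at both
placements; wrist values are systematically higher and are therefore always
reported per placement, never pooled with waist.

1. **MET rate** — per-epoch energy expenditure in metabolic equivalents
   (1 MET = 3.5 mL O2/kg/min, the resting rate).  Epochs above the moderate
   threshold use the Freedson walking regression
   `METs = 1.439008 + 0.000795 * CPM`; lighter epochs contribute the 1-MET
   floor.  The summary is the mean over wear epochs, hence always >= 1 and
   non-decreasing in counts.
2. **Activity bouts** — maximal runs of >= 10 consecutive wear minutes at
   moderate-or-vigorous intensity.  The default is strict (0 dropped
   minutes); a drop-time tolerance can be enabled, in which case absorbed
   sub-threshold minutes count toward bout duration and excluded epochs
   always split a bout.
3-5. **Intensity percentages** — shares of wear time in sedentary, light and
   pooled moderate/vigorous (MVPA) intensity; they sum to 100 exactly.  Wear
   time (not nominal protocol time) is the denominator, which makes the
   percentages robust to how much of the waking day was actually recorded.
6. **VM3** — mean over wear epochs of the 3-axis vector norm, in CPM.  It is
   the least processed measure (no cut-points, no regression), and by the
   triangle inequality it always dominates the mean vertical CPM.
7. **Steps/min** — total steps divided by total wear minutes.

## Cohort statistics

* **Group comparison** — Shapiro-Wilk on each group at alpha = 0.05 gates
  the test: both normal -> Welch's t, otherwise Mann-Whitney U (two-sided).
  Constant samples take the rank path.
* **Multiplicity** — Bonferroni over the family of 7 distinct measures.
  Because waist and wrist versions of a measure are strongly correlated,
  they share one family slot (both p-values are multiplied by 7, not 14).
* **Correlation** — Spearman's rho between digital measures and clinical
  scores (SARA, mFARS, ADL, CCFS, disease duration), pairwise-complete.
* **Longitudinal change** — paired t or Wilcoxon signed-rank on follow-up
  minus baseline, with the same normality gate applied to the change scores
  and Wilcoxon as the tie-break when the gate cannot decide; subjects
  missing a visit are dropped pairwise.
* **Reliability** — odd (Mon/Wed/Fri) vs even (Tue/Thu/Sat) weekday halves
  of the baseline week, Sundays excluded, each half summarized
  independently; ICC(2,1) (two-way random effects, absolute agreement,
  single measure) from the two-way ANOVA mean squares.  This form is the
  standard choice for test-retest of a continuous measure when both halves
  should agree in absolute value, not merely rank subjects consistently.
  `SEM = sd * sqrt(1 - ICC)` (ICC clipped at 0 so the SEM stays real) and
  `MDC95 = 1.96 * sqrt(2) * SEM`.
* **Responsiveness** — standardized response mean `SRM = mean(change) /
  sd(change)`, with the conventional labels large (>= 0.8), moderate
  (0.5-0.8), low (< 0.5).
* **Trial sizing** — per-arm n for a two-arm trial detecting a fraction
  `delta` of the observed standardized change at two-sided alpha = 0.05 and
  80% power: `n = ceil(2 * (z_{1-a/2} + z_{pow})^2 / (delta * SRM)^2)`.
  The default is `delta = 1`, because published per-arm numbers for this
  design are numerically consistent with the effect equalling the SRM
  itself (e.g. SRM 0.09 -> 1938 by the closed form vs 1940 printed) even
  when the accompanying text speaks of a 50% slowing of progression;
  `delta = 0.5` is available by flag.  A noncentral-t solver
  (`solver="t"`) is provided as an alternative; published values sit within
  a few percent of the normal approximation at the small-SRM end, so only a
  10% band is asserted against them.

## Synthetic cohort model

Participant-level recordings from such studies are typically not public, so
the generator produces cohorts with the statistical structure the analysis
assumes, calibrated to published cohort-level anchors.

* **States and dynamics** — a minute-resolution first-order Markov chain
  over {sedentary, light, moderate, vigorous} within a 16-h waking window
  (06:00-22:00).  The transition matrix is the persistence mixture
  `kappa*I + (1-kappa) * 1 pi^T` with `kappa = 0.85`, whose stationary law
  is exactly the profile occupancy `pi`; mean dwell time is ~6.7 min, long
  enough to yield 10-min MVPA bouts at control occupancies.  A semi-Markov
  model with realistic dwell distributions was deliberately not used: dwell
  realism is not needed for any quantity the pipeline reports.
* **Occupancy calibration** — group x placement stationary occupancies are
  anchored to the published group means (waist sedentary 81.3% FRDA vs
  67.7% controls; wrist 42.9% vs 31.7%, etc.).  Wrist profiles are separate,
  with higher occupancy of active states and higher count levels, encoding
  the observation that wrist-worn sensors record more activity than waist
  sensors in patients and controls alike.
* **Severity linkage** — SARA is drawn N(17.2, 6.0) for patients (controls
  0-1).  Standardized severity tilts the sedentary dwell up
  (slope +0.45 on the logit) and the MVPA share of non-sedentary time down
  (-0.35), producing Spearman correlations of SARA with waist sedentary
  time around 0.8.  Other clinical scores (mFARS, ADL, CCFS, the FARS
  upright-stability subscore, gait subscore, 8MWT with severity-dependent
  missingness) are noisy monotone maps of SARA so the sub-score analyses
  are exercisable.
* **Noise structure** — subject-level (sd 0.28), day-level (sd 0.40) and
  visit-level (sd 0.08) Gaussian perturbations on the sedentary logit.
  Because a symmetric logit perturbation shrinks the mean probability
  toward 1/2 (Jensen), each noise level carries a numerically solved
  intercept correction that keeps expected occupancies on their calibration
  anchors.  The day-level variance is the lever that sets the odd/even
  split-half ICC; 0.40 puts waist ICCs in the 0.8-0.9 range typical of
  week-long actigraphy, and it is a synthetic choice, not an estimate of
  real day-to-day behaviour.
* **Counts, steps, non-wear** — vertical counts are truncated log-normals
  confined to the intensity band of their state, so generated labels are
  exactly recoverable from the counts (classification error 0 by
  construction); lateral axes are noisy scalings (ratios 0.55/0.40,
  log-normal noise sd 0.25) chosen to land VM3 near the published group
  means.  Steps are Poisson in light and MVPA states only, with rates
  solved from the linear calibration `rate_l*p_l + rate_m*p_m = target`
  (MVPA rate fixed at 3x light, cadence ~90/min).  In the sedentary state
  counts are drawn from [1, 99] CPM: true zeros occur only during non-wear,
  which makes wear detection on synthetic data exact and is the main
  deliberate departure from real data (real sedentary time contains zero
  epochs, so real-data wear detection is noisier than these tests show).
  With probability 0.35 per day a 90-150-min zero block is inserted as
  ground-truth non-wear.
* **Decline** — at follow-up (52 weeks later, same weekday) patient SARA
  worsens by N(1.5, 1.5) and patient profiles additionally shift +0.10
  logit toward sedentary and -0.10 on the MVPA share, scaled by the
  `annual_decline` multiplier (0 disables both and restores the
  longitudinal null); controls are unshifted.  This yields ~+3 points of
  sedentary time and ~-15% VM3 over one year, with SRMs near the published
  0.7-0.8.

### What passing tests do and do not show

Synthetic recovery demonstrates that the pipeline's algorithms are correct
and that the statistical battery detects the programmed structure at the
study's sample sizes.  It does not validate the behavioural realism of the
Markov model, the device count model, or the proprietary steps algorithm,
and exact published correlation/ICC/SRM values are not reproduction targets
because they depend on participant-level data that are not public.

## Numerical choices and degenerate inputs

* Exact cut-point values sit on the lower bin edge of the next class
  (e.g. 1952 CPM is moderate); exactly 90 min of zeros is non-wear;
  exactly 8 h of wear is a valid day.
* Constant samples: Shapiro-Wilk is undefined, so gated tests fall back to
  the rank path; an all-zero change vector reports p = 1; zero change
  variance makes SRM (and the trial size) an error rather than infinity;
  zero total variance makes the ICC an error.
* ICC uses the ANOVA closed form; it equals pingouin's ICC(A,1) to 1e-10 on
  random tables (checked in the test suite).
* A series shorter than one non-wear window is returned all-wear with a
  warning; empty analysis masks raise rather than emit NaN measures.
* Problem sizes in the validation suite (200-1000 random sequences per
  oracle check, 60-100 replicate cohorts, n = 10^5 draws for SRM
  convergence) were chosen so every Monte-Carlo band is several standard
  errors wide.

## Known limitations

* First-order dwell dynamics and band-confined counts make synthetic data
  cleaner than device exports; real recordings will exercise the non-wear
  detector and cut-point classifier harder.
* The MET regression is a walking-calibrated adult equation; in a
  population with ataxic gait it is an approximation, used here because the
  study design reports MET rate from counts without a disease-specific
  model.
* Bonferroni with a shared waist/wrist family is conservative for the
  correlated measures within a placement and anti-conservative across
  placements in the unlikely case they decorrelate.
* The pipeline does not model missing visits beyond pairwise deletion, and
  no mixed-effects longitudinal model is fitted.
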
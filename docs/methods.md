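# Methods

## Data model

The unit of analysis is the **anchor–outcome pair**: one (change score,
state score, anchor response) triple per patient per follow-up. With four
registered instruments (NRS pain 0–10, PRWHE pain 0–50, PRWHE function
0–50 in half points, PRWHE total 0–100), all scored lower-is-better, the
change score is Δ = baseline − follow-up so that positive Δ means
improvement, and Δ + state = baseline holds exactly for every pair.
PRWHE scoring follows the instrument's published rule: pain = sum of items
1–5; function = sum of items 6–15 divided by two (the only rule under
which ten 0–10 items map onto a 0–50 subscale); total = pain + function.
Pairs are pooled across the five follow-ups; per-timepoint subsets are
available but flagged below a configurable floor (default 10 pairs).
Missing data are handled by pairwise deletion — a pair lacking the score
or the anchor required by a given analysis is dropped from that analysis
only, and counted in an exclusion log.

## Anchor credibility

Spearman's ρ (Pearson correlation of mid-ranks; the GRC is treated as
ordinal 1–5 with heavy ties) is computed between the GRC and (a) the
baseline score, (b) the follow-up score, (c) the change score, each with a
percentile bootstrap CI. The credibility flag applies |ρ_change| > 0.5:
the absolute value is used because GRC code 1 is the *best* response, so a
credible anchor correlates negatively with improvement. The baseline and
follow-up correlations are reported without a pass/fail judgement — no
accepted threshold exists for them.

## MID estimators

GRC dichotomization for the ROC and predictive methods: improved =
{much better, somewhat better}, reference = {unchanged}, deteriorated
responses excluded. The cut between "unchanged" and "somewhat better"
places "much better" on the improved side; the partition is configurable.
MC and MDC deliberately use the "somewhat better" group alone, per the
definitions of those methods.

* **ROC.** Candidate thresholds sit at midpoints between adjacent distinct
  observed values, plus one degenerate endpoint on each side — this is
  what yields half-unit thresholds (e.g. 2.5) on an integer change scale.
  The optimum minimizes distance to the (0, 1) corner; exact ties break
  toward higher sensitivity (favouring detection of improvement), then
  toward the smaller absolute threshold. Both rules are deterministic.
* **Predictive modelling.** Maximum-likelihood logistic fit of the
  dichotomized anchor on Δ. The reported MID is the prevalence-adjusted
  likelihood-ratio-1 point (ln(pre-odds) − C)/B, derived from
  posterior-odds = pre-odds · exp(C + B·Δ); with balanced classes it
  reduces to −C/B, which is also always reported. A non-positive slope or
  a non-convergent / separated fit is an error that directs the user to
  the ROC method.
* **Confidence intervals.** Percentile bootstrap, 1000 replications by
  default, re-running the full estimator (cut-point selection, logistic
  re-fit) on every resample. MDC resamples its two anchor groups
  independently. AUC intervals use DeLong's structural-components
  variance; perfect separation gives a zero-variance degenerate interval
  with a warning rather than an error.

## PASS estimators

PASS is a state concept, so both methods use follow-up state scores, never
change scores. The 75th-percentile method applies the linear-interpolation
quantile (order-statistic index h = (n−1)p + 1); with ~125 satisfied pairs
the choice of quantile definition moves the result by less than one score
unit. The ROC method orients lower-score-positive: sensitivity is the
fraction of satisfied pairs at or below the threshold, specificity the
fraction of unsatisfied pairs above it. Pooling across timepoints is the
default for symmetry with the MID analysis; a final-timepoint-only scope
is available.

## Bootstrap resampling unit

The default resampling unit is the pair, matching the pooled-pair analysis
the estimators implement. Because the five pairs a patient contributes are
positively correlated (they share the patient's recovery trajectory), the
pair-level interval is mildly anticonservative; a patient-level cluster
bootstrap (`bootstrap_unit="patient"` / `units=` in `bootstrap_ci`) is
provided and is the better choice when within-patient correlation is a
concern. In the generator's regime the pair-level 95% interval for
ρ_change covers the population value in about 89% of replicates and the
cluster interval in about 91% — the coverage test therefore resamples
patients.

## Synthetic cohort generator

The generator provides ground truth for recovery tests and a stand-in for
cohorts that cannot be shipped. Per patient i and follow-up t:

* latent recovery fraction s(i,t) = r(t) + u_i, with a monotone mean curve
  r(t) = (0.10, 0.45, 0.55, 0.60, 0.65) across the five follow-ups and a
  patient random effect u_i ~ N(0, 0.25²);
* baseline severities are truncated normals with means/SDs 6.5 (1.7) for
  NRS, 34.2 (6.8) and 30 (7.9) for the PRWHE subscales, correlated across
  instruments through a shared severity factor (r = 0.5); the total is the
  subscale sum by construction;
* observed follow-up score = clip(baseline − s·gain + noise) rounded to
  the instrument's granularity, with full-recovery gains (6.5, 29, 27) and
  observation noise SDs (0.9, 3.0, 3.5) for NRS / PRWHE pain / function;
* the GRC derives from the *latent* recovery plus anchor noise
  (SD 0.12), discretized at thresholds (−0.35, −0.05, 2.5/6.5, 0.55) — so
  the anchor reflects true improvement, not the observed change, which is
  what makes discrimination imperfect (AUC < 1) as in real cohorts;
* the satisfaction anchor is a logistic draw on the range-normalized sum
  of (state − location) across instruments, locations (2.5, 15, 11) and
  scale 0.10;
* missingness, when enabled, is completely at random at follow-ups only.

The implied ground truth is MID_k = (2.5/6.5)·gain_k — 2.5 NRS points,
11.2 / 10.4 / 21.5 PRWHE points — and PASS_k = location_k. The noise
levels were calibrated once so that the default cohort lands in the regime
the estimators are meant for: |ρ_change| ≈ 0.7–0.87, MID AUC ≈ 0.84–0.95,
ROC-PASS at or slightly above percentile-PASS, and MID magnitudes of
roughly 20–30% of each instrument's range.

What the generator does **not** emulate: informative (outcome-dependent)
missingness, serial correlation beyond the single random effect,
treatment-phase structure (splinting vs surgery as distinct effects),
response styles in anchor answering, or floor effects beyond simple range
clipping. Passing recovery tests therefore demonstrates estimator
correctness under these stated assumptions, not robustness to every
feature of real registry data.

## Problem sizes and determinism

The test suite runs the full pipeline at the study scale (50 patients, 250
pairs, 1000 bootstrap replications), parameter recovery at 500 pairs over
50 generator draws, and bootstrap coverage over 200 replicates of 250
pairs — sizes chosen so the whole suite completes in a few minutes while
keeping Monte-Carlo error well below the asserted margins. Every source of
randomness takes an explicit seed; identical seeds give byte-identical
cohorts, intervals and artifacts, and the CLI records seed, configuration,
exclusion counts and warnings in a manifest sufficient to reproduce a run.

## Known limitations

* Pair-level CIs ignore within-patient correlation unless the cluster
  bootstrap is selected (see above).
* The predictive-modelling MID assumes the logistic model is correctly
  specified in Δ alone; strong non-linearity would bias it where the ROC
  method would not.
* MDC is shift-invariant (a difference of two group means), so unlike the
  other three estimators it cannot detect a uniform shift of all change
  scores; this is a property of the method, not of the implementation.
* No deterioration-direction thresholds, no distribution-based MID
  methods (SEM, 0.5·SD), and no imputation — all deliberately out of
  scope.
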
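# midpass

Anchor-based estimation of the **minimal important difference (MID)** and the
**patient acceptable symptom state (PASS)** for patient-reported outcome
measures, built for longitudinal cohorts scored on **NRS pain** (0–10) and the
**Patient-Rated Wrist/Hand Evaluation (PRWHE)** (pain and function subscales
0–50, total 0–100; lower is better on every scale).

Raw instrument scores are hard to interpret on their own. Two clinimetric
thresholds make them actionable: the MID — the smallest *change* in score
that patients themselves perceive as an improvement — and the PASS — the
*state* score below which patients consider their symptoms acceptable. Both
are estimated against external anchor questions asked at follow-up: a
five-level global rating of change (GRC: much better / somewhat better /
unchanged / somewhat worse / much worse) for the MID, and a yes/no
"would you be satisfied if your condition stayed like this?" question for
the PASS. The package is aimed at clinical researchers interpreting
hand-surgery and osteoarthritis trials, but every estimator is generic over
any lower-is-better bounded scale registered with it.

## Methods implemented

With change scores Δ = baseline − follow-up (positive = improvement) pooled
across all follow-up timepoints, and the GRC dichotomized between
"unchanged" and "somewhat better" (deteriorated responses excluded):

* **MC** — mean Δ among "somewhat better" pairs;
* **MDC** — mean Δ("somewhat better") − mean Δ("unchanged");
* **ROC** — the candidate threshold (midpoints between adjacent distinct
  scores) closest to the top-left corner of ROC space, i.e. minimizing
  √((1−sens)² + (1−spec)²), with AUC and a DeLong 95% CI;
* **predictive modelling** — fit logit P(improved) = C + B·Δ; the MID is the
  change value where the likelihood ratio for improvement equals 1,
  MID = (ln(pre-odds) − C)/B with pre-odds = n_improved/n_reference
  (the unadjusted −C/B variant is reported alongside);

and for the PASS, from follow-up *state* scores and the satisfaction anchor:

* **75th percentile** of the state-score distribution of satisfied pairs
  (linear-interpolation quantile);
* **ROC** — the cut point separating satisfied from unsatisfied pairs,
  oriented so that lower scores call "acceptable".

Anchor credibility is checked first: Spearman's ρ between the GRC and the
change score must exceed 0.5 in absolute value (the GRC codes 1 = best, so a
credible anchor correlates *negatively* with improvement). Confidence
intervals are percentile bootstrap intervals (default 1000 replications)
resampled at the pair level, with a patient-level cluster bootstrap
available because the five pairs a patient contributes are correlated.

A fully parameterized synthetic-cohort generator
(`midpass.simulate`) reproduces the statistical structure these estimators
assume — latent recovery, an imperfect ordinal anchor, a logistic
satisfaction anchor — with known ground-truth MID and PASS, and is used
throughout the test suite for parameter-recovery checks.

## Worked example

```sh
midpass all --seed 1 --n-boot 1000 --out-dir demo_run
```

simulates the default 50-patient cohort (baseline + 5 follow-ups, 250
anchor–outcome pairs), validates the anchor, and writes the MID, PASS and
correlation tables plus a manifest. The summary begins:

```
MID estimates (change units; 95% CI)
  nrs              mc         3.0 (2.6 to 3.3)
  nrs              mdc        1.3 (0.9 to 1.7)
  nrs              roc        2.5 (2.5 to 2.5)
  nrs              predictive 2.6 (2.5 to 2.8)
  ...

PASS estimates (state units)
  nrs              percentile75 2.0
  nrs              roc          2.5  sens 0.76 spec 0.84 auc 0.88 (0.83 to 0.92)
  ...

Anchor credibility (pooled Spearman rho with GRC)
  nrs              rho_change -0.73 (-0.79 to -0.66) credible=True
```

Reading: a 2.5-point drop in NRS pain is the smallest change patients rate
as improvement by the ROC method (the generator's true value is 2.5), an
NRS state of 2.5 or less is an acceptable symptom state, and the anchor is
credible (|ρ| = 0.73 > 0.5). The same pipeline runs on your own data with
`--input cohort.csv`; the expected header is
`patient_id,timepoint,nrs,prwhe_pain,prwhe_function,prwhe_total,grc,pass_satisfied`
(plus optional `prwhe_item_01..15` and free covariate columns), one row per
patient × timepoint, timepoints labelled `baseline, post_splint_6wk, m3,
m6, m9, m12`, GRC as codes 1–5 or labels, and `pass_satisfied` as yes/no.

The same analyses are available as library calls: `build_pairs`,
`validate_anchor`, `mid_mc/mid_mdc/mid_roc/mid_predictive` (or `mid_all`),
`pass_percentile/pass_roc` (or `pass_all`).

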
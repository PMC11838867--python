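# Methods

This note documents the analysis rules, the synthetic-data generator, the
statistical machinery, and the numerical choices the package makes — in the
spirit of a model-description appendix.

## Date and window conventions

Dates are ISO calendar dates; all interval arithmetic is in whole days.
Windows are closed on the left and open on the right, except rules phrased
as "between X and Y", which are closed on both ends.  Concretely:

| rule | window |
|---|---|
| pre-index diabetes evidence | entire available history before the index date |
| sub-diagnostic lab requirement | [index − 730 d, index) |
| outpatient-visit requirement | [first of index month − 365 d, first of index month) |
| post-index glucose exclusion | [index, index + 30 d], glucose kinds only |
| hospitalization | [index − 7 d, index + 30 d], closed-closed |
| prior-year utilization counts | [index − 365 d, index) |
| remission latency / gap | t1 ≥ detection + 90 d; t2 − t1 ≥ 90 d |

The visit requirement is anchored to the index *month* (the stricter of the
two phrasings in circulation for this rule); pre-index evidence uses the full
history because the 2-year lookback belongs to the sub-diagnostic-lab
requirement only.

## Index assignment and frequency matching

Exposed: index = date of the first positive swab.  Unexposed: candidate
months are calendar months containing ≥ 1 laboratory test (or ≥ 1 negative
swab under the negative-swab comparator) and also containing exposed index
dates; month quotas are computed from the exposed index-month histogram by
largest remainder, months are filled scarcest-first by sampling candidates
without replacement, leftover patients draw a candidate month weighted by
the exposed histogram, and the index *day* is uniform over all days of the
assigned month (lab days define candidacy only).  Patients with no candidate
month are dropped and logged.  At n = 10,000 the total-variation distance
between arm index-month distributions is below 0.03 (tested).

A consequence worth knowing: an unexposed patient can be assigned an index
month later than their (latent) diabetes onset; the eligibility gates then
remove them as prevalent disease.  This mirrors the real mechanism — a
random lab-month index is assigned before exclusions — and lowers the
unexposed diabetic yield relative to exposed, without biasing the remission
comparison among included patients (verified by parameter recovery).

## Detection and remission details

Cohort-1 criterion dates: second qualifying abnormal lab, first in-range
ICD-10 code (a single code suffices; E08–E13, never E14), second fill of a
glucose-lowering prescription whose initial fill is on/after index and whose
fills share one prescription id.  The earliest satisfied criterion wins;
ties break labs → code → medications.  HbA1c is not subject to the 30-day
glucose exclusion, and that exclusion is applied post-index only (its stated
purpose is corticosteroid treatment of the acute illness).

Remission: HbA1c equal to the threshold does **not** qualify (strict "<");
diagnostic checks use "≥".  Medication disqualification at a candidate date
t means: t lies inside a dispensed-supply interval, or the latest fill (per
prescription) on or before t left refills outstanding — a prescription whose
last fill has refills remaining stays open indefinitely.  The
no-subsequent-diabetes-lab rule is enforced from t1 onward (the stricter
body-text reading, which implies the between-t1-and-t2 variant); the weaker
variant is available as `between_only=True`.  The reported pair is the
lexicographically earliest qualifying pair; the classifier is tested against
an O(n²) enumeration oracle on thousands of random event streams.

Follow-up is the date of the last recorded event of any kind minus the index
date, floored at zero.

## The synthetic EHR generator

The generator emulates an *enriched study population*, not population-level
disease frequencies: every patient has background care, a configurable
fraction (`p_incident_diabetes`, default 0.30) develops incident diabetes
after a latent anchor date, and 5% carry prevalent diabetes to exercise the
exclusion gates.  Default demographics (age 60.5 ± 13, 11% female, race
indicator frequencies, BMI 33.6 ± 6.6 with 10% MCAR missingness, Charlson ~
Poisson(1)) match the descriptive profile of the veteran cohorts this
pipeline is aimed at.  Exposure (`p_exposed` = 0.25) assigns a first
positive swab at an anchor drawn from a wave-shaped era mixture
(wild-type-heavy); unexposed anchors sit at their anchor month's end so that
frequency-matched index days precede detection events.

Event processes are Poisson with per-patient rates (visits 18/yr; glucose
3/yr pre-index, 6/yr post; HbA1c 2/yr post) and laboratory values are
Gaussian around state-dependent means, truncated to the type invariants:
healthy HbA1c 5.5 ± 0.3 (< 6.5), pre-detection prediabetes 6.0 ± 0.25,
diabetic 7.3 ± 0.6 (≥ 6.5), remitted 5.9 ± 0.3 (< 6.5).  Each glucose test
of a patient in a non-diabetic regime has a small transient-hyperglycemia
spike probability (default 0.01); two spikes outside the 30-day window can
falsely satisfy the computable phenotype, which is precisely how
surveillance bias enters.  Post-index laboratory intensity of exposed
patients is multiplied by `surveillance_ratio` (default 1.0 — neutral study
conditions; the bias simulation raises it, optionally only for hospitalized
exposed patients via `surveillance_hospitalized_only`).

Latent remitters are drawn among incident diabetics with probability
`p_remission_base` (0.19) times `true_remission_rr` (default 1.25) for the
exposed; the generator then emits a definition-satisfying trajectory —
remission onset 90+ days after detection, a guaranteed sub-threshold HbA1c
pair ≥ 90 days apart squeezed inside the data horizon, normal glucose with
no spikes after onset, and any medication chain closed (last refill 0) well
before the first qualifying measurement.  Remitters whose detection falls
too close to the administrative data horizon (2022-12-31) cannot exhibit a
qualifying pair; under the defaults this affects ~1–2% of remitters,
nondifferentially by arm, so ≥ 95% of latent remitters classify as remission
(tested).  A ground-truth sidecar (`truth.csv`: latent flags, anchor and
planned detection dates) is written for tests only; no analysis stage reads
it.

What the generator does *not* emulate: real VHA schemas, ICD-code-level
comorbidity structure, care-seeking feedback loops, inpatient medication
administration, assay error structure, or informative BMI missingness
(missingness is MCAR, matching the imputation setting).  Mean follow-up in
generated cohorts (~840 days) runs longer than the ~500 days of the source
setting because the horizon is fixed rather than staggered by data pull.
Passing tests therefore demonstrate that the *rules and estimators* behave
correctly under the stated data-generating assumptions, not that real EHR
data meet those assumptions.

## Models

The primary model is a binomial GLM with log link fit by IRLS (tol 1e-12),
so coefficients exponentiate to relative risks; on a saturated 2×2 design it
reproduces the empirical risk ratio to 1e-8 (tested).  Adjustment terms:
age category (ref 50–59), female sex, four non-exclusive race/ethnicity
indicators, BMI category (ref 30–34, "24–29" read as [24, 30) so bins are
contiguous), Charlson index and prior-year HbA1c count as continuous linear
terms, pandemic era (ref wild type, 3/2020–4/2021 .. 1/2022–6/2022),
vaccine-dose category (ref 0), and region (ref Other).  α = 0.05, no
multiplicity correction.

Numerical safeguards: collinear design columns are removed by rank-revealing
QR; indicator levels with zero (or all) events are dropped, and if a
categorical reference cell has zero events the term is re-referenced to its
largest-event level — all logged.  If the log-link fit still fails to
converge or fits probabilities at 1, the model is refit as a Poisson rate
model with HC0 robust variance and flagged `poisson_robust_fallback`.
Degenerate inputs (a constant outcome, an empty exposure-outcome cell) raise
an estimation error naming the cell rather than returning a silent estimate.

BMI imputation: normal linear regression of observed BMI on all adjustment
covariates plus the outcome; each of the m = 10 imputations draws σ² from
its scaled inverse-χ² posterior and β from N(β̂, σ²(XᵀX)⁻¹), adds residual
noise, truncates to [12, 80] kg/m², and re-derives the BMI category.  With
no missing values the pooled analysis is exactly the complete-data fit.
Pooling uses Rubin's rules (T = W̄ + (1 + 1/m)B) with a normal-reference CI.

## Problem sizes used in the test suite

Distributional checks run at n = 10,000; parameter recovery and type-I
error at n = 20,000 patients × 100 replicates each (coverage ≥ 93%, false
exclusion ≤ 7%); the surveillance-bias demonstration at n = 4,000 × 50
replicates with `surveillance_ratio` 6 on hospitalized exposed patients
only; oracle equivalence on 1,000+ random streams.  These sizes give
Monte-Carlo error comfortably inside the asserted margins while keeping the
default test run short.

## Known limitations

* The unexposed arm's laboratory-frequency parameters are free knobs; no
  public calibration target exists for them.
* Era-level confounding by data-horizon censoring is only partially absorbed
  by the era covariate; at the defaults the residual bias on the exposure RR
  is ≲ 1% of the effect (measured in the recovery tests).
* The frequency-matching algorithm satisfies month quotas greedily
  (scarcest month first); with pathological candidacy patterns quotas may be
  unfillable, in which case the shortfall spills to the patients' remaining
  candidate months.
* Vital-sign counts are proxied by encounter counts (the table set carries
  no separate vitals stream).
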
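# remitehr

Computable-phenotype diabetes cohorts, EHR-defined remission classification,
and log-binomial relative-risk analysis on longitudinal electronic health
record (EHR) event tables — with a synthetic EHR generator so that the whole
pipeline is testable without access to restricted clinical data.

## The scientific problem

Observational EHR studies have asked whether SARS-CoV-2 infection changes
long-term glycemia, and in particular whether adults whose diabetes is first
detected after a positive swab go on to *remission* — sustained
sub-diagnostic glycemia off glucose-lowering medication — more or less often
than comparable uninfected adults.  Answering this from raw EHR event
streams requires a chain of carefully specified rules:

1. **Index dates.** Exposed patients are indexed at the date of their first
   positive SARS-CoV-2 swab; unexposed patients receive a random date during
   a month in which they had any laboratory test, with the unexposed
   index-month distribution *frequency matched* to the exposed distribution
   so the two arms accrue comparable follow-up.
2. **Eligibility.** Patients with any pre-index evidence of diabetes (random
   glucose ≥ 200 mg/dL, fasting glucose ≥ 126 mg/dL, 2-h OGTT glucose
   ≥ 200 mg/dL, HbA1c ≥ 6.5%, or an ICD-10 code E08–E13) are excluded, as
   are patients without a sub-diagnostic glucose/HbA1c result in the prior 2
   years or an outpatient visit in the year before the index month.
3. **Incident diabetes.** Two computable phenotypes: *cohort 1* — two or
   more abnormal post-index lab values (glucose values within 30 days of the
   index date are ignored to avoid corticosteroid-related transient
   hyperglycemia), or a diabetes ICD-10 code, or an initial plus one refill
   dispense of a glucose-lowering medication; *cohort 2* — two post-index
   HbA1c results ≥ 6.5%.  Both cohorts are restricted to patients with ≥ 2
   HbA1c results after detection, so remission is observable in principle.
4. **Remission.** ≥ 2 HbA1c measurements < 6.5% (strict) at least 90 days
   apart, the first ≥ 90 days after detection, with neither measurement
   inside a medication-supply interval or while a glucose-lowering
   prescription has refills outstanding, and no diabetes-range lab value on
   or after the first qualifying measurement.
5. **Inference.** Risk of remission is modelled with a log-binomial GLM
   (coefficients exponentiate to relative risks, RR = exp β), adjusted for
   age, sex, race/ethnicity indicators, BMI category, Charlson index,
   prior-year HbA1c count, pandemic era, vaccine doses and region; BMI is
   multiply imputed (m = 10) and estimates pooled by Rubin's rules
   (T = W̄ + (1 + 1/m)·B).  Sensitivity analyses rerun remission at
   HbA1c < 5.7%, restrict to non-hospitalized patients, and rebuild the
   comparator from prior-negative-swab patients.

Because testing intensity differs by exposure (hospitalized COVID patients
are surveilled more), the package also ships a surveillance-bias simulation:
extra testing of hospitalized exposed patients inflates the apparent
remission RR even when the true effect is null, and the non-hospitalized
subgroup estimate falls back toward 1 — the attenuation pattern that
motivates the subgroup analysis.

## Worked example

```python
from remitehr import (GeneratorConfig, generate_dataset, build_cohort,
                      classify_cohort, derive_rows, fit_pooled)

ds = generate_dataset(GeneratorConfig(n_patients=20_000, seed=1))
build = build_cohort(ds, cohort_id=1, seed=2)
print(build.gate_counts)
rem = classify_cohort(ds, build.cohort)
rows = derive_rows(ds, build.cohort, rem)
rr = [r for r in fit_pooled(rows, m=10, seed=3) if r.term == "exposed"][0]
print(f"remission: {rows['remission'].mean():.1%}  "
      f"adjusted RR {rr.rr:.2f} (95% CI {rr.ci_low:.2f}-{rr.ci_high:.2f})")
```

prints

```
{'n_input': 20000, 'prior_diabetes': 2783, 'no_normal_lab_2y': 102,
 'no_visit_1y': 2114, 'no_incident_diabetes': 10287,
 'fewer_than_2_post_detection_a1c': 60, 'n_output': 4654}
remission: 21.5%  adjusted RR 1.21 (95% CI 1.08-1.36)
```

Reading: of 20,000 synthetic patients, 4,654 enter the incident-diabetes
cohort after the eligibility gates (each count is the number removed at that
gate); 21.5% meet the remission definition; and the pooled adjusted
relative risk of remission for exposed vs unexposed patients is 1.21 —
consistent with the generator's configured true effect of 1.25 (the CI
covers it).

The same run is available as a command-line pipeline:

```bash
remitehr run --config config.yaml      # or: remitehr generate / phenotype / analyze
```

where `config.yaml` holds the `RunConfig` fields (`generator:` block or
`data_dir:`, `cohorts:`, `sensitivity:`, `m_imputations:`, `output_dir:`,
`seed:`).  Outputs: `cohort.csv`, `remission.csv`, `analysis_table.csv`,
`table1.csv`, `table2.csv`, `results.json`, `exclusions.csv`, `run_log.txt`.

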
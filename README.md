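# miascore

Identification of the ruptured aneurysm in patients with **multiple
intracranial aneurysms (MIAs)** and subarachnoid hemorrhage, using the
**aneurysm-specific prediction score**, together with the full
diagnostic-accuracy machinery needed to validate it on a cohort.

## Who this is for

When a patient presents with an aneurysmal subarachnoid hemorrhage and CT
angiography shows more than one aneurysm, the treating team must decide
which lesion bled. The aneurysm-specific prediction score is a simple
linear score over three CTA measurements that ranks a patient's aneurysms;
the highest-scoring one is predicted to be the ruptured aneurysm (RIA).
This package is for biostatisticians and clinical researchers who want to
apply that score to their own tabular cohort data, reproduce its published
validation metrics, or stress-test it on simulated cohorts.

## The score

For one aneurysm with maximum diameter *d* (mm), location *L* and shape *S*:

```
score = A + B + C
A = 0.0427 · d
B = 0        if L ∈ {AcomA, AA}      (anterior communicating / cerebral)
  = −0.0104  if L = PcomA            (posterior communicating)
  = −0.1831  if L = PC               (posterior circulation)
  = −0.4055  if L = MCA              (middle cerebral)
  = −0.5973  if L = ICA              (internal carotid)
C = 0 (regular shape)  or  0.5387 (irregular shape)
```

Within each patient the aneurysm with the largest score is predicted
ruptured. The package evaluates this rule against the single-feature
competitors (largest diameter, irregular shape, location membership) with
aneurysm-level sensitivity, specificity, their complements β and α,
diagnostic accuracy, and ROC/AUC (DeLong or bootstrap confidence
intervals). A seeded generator simulates validation cohorts with the
published cohort structure (134 patients, 290 aneurysms, exactly one
ruptured per patient).

## Worked example

Cohort CSVs have one row per aneurysm with columns
`patient_id, aneurysm_id, diameter_mm, location, shape, ruptured`.
The package ships the 17-patient cohort in which the score picked the
wrong aneurysm (the published misidentified-patient table):

```python
from miascore import table3_fixture, write_cohort
write_cohort(table3_fixture(), "table3.csv")
```

Scoring it appends the three components and the total:

```sh
$ mia score --input table3.csv --out scored.csv
$ head -3 scored.csv
patient_id,aneurysm_id,diameter_mm,location,shape,ruptured,component_A,component_B,component_C,score
1,1a,7.9,PcomA,irregular,no,0.33733,-0.01040,0.53870,0.86563
1,1b,7.6,PcomA,irregular,yes,0.32452,-0.01040,0.53870,0.85282
```

Patient 1's unruptured aneurysm (score 0.86563) outranks the ruptured one
(0.85282) — which is exactly why this patient is in the misidentified set.
Evaluating a simulated cohort drawn at the study conditions shows the score
rule beating every single-feature rule:

```sh
$ mia simulate --out sim.csv --seed 1        # 134 patients / 290 aneurysms
$ mia evaluate --input sim.csv --out reports
$ sed -n '7,16p' reports/report.md
| rule | TP | FP | FN | TN | SEN | SPE | beta | alpha | DA |
|---|---|---|---|---|---|---|---|---|---|
| diameter_largest | 102 | 33 | 32 | 123 | 76.1 | 78.8 | 23.9 | 21.2 | 77.6 |
| shape_irregular | 96 | 34 | 38 | 122 | 71.6 | 78.2 | 28.4 | 21.8 | 75.2 |
| location_PC | 5 | 9 | 129 | 147 | 3.7 | 94.2 | 96.3 | 5.8 | 52.4 |
| location_AcomA+AA | 31 | 16 | 103 | 140 | 23.1 | 89.7 | 76.9 | 10.3 | 59.0 |
| location_PcomA | 64 | 40 | 70 | 116 | 47.8 | 74.4 | 52.2 | 25.6 | 62.1 |
| location_MCA | 33 | 44 | 101 | 112 | 24.6 | 71.8 | 75.4 | 28.2 | 50.0 |
| location_ICA | 1 | 47 | 133 | 109 | 0.7 | 69.9 | 99.3 | 30.1 | 37.9 |
| score_largest | 119 | 15 | 15 | 141 | 88.8 | 90.4 | 11.2 | 9.6 | 89.7 |
```

Here the score rule misidentifies the ruptured aneurysm in 15 of 134
simulated patients (sensitivity 88.8%, specificity 90.4%, diagnostic
accuracy 89.7%) — closely matching the published validation figures of
87.3% / 89.1% / 88.3% with 17 of 134 patients misidentified. The report
also contains an AUC table for the three score components and the total
score, and the list of misidentified patient ids (`reports/report.json`
holds the same content machine-readably).

The same analyses are available as library calls: `compute_score`,
`predict`, `misidentified_patients`, `evaluate_all_rules`, `roc`,
`cohort_summary`, `cohens_kappa`, `generate` — see the module docstrings
and `docs/methods.md`.

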
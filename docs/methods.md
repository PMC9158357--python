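# Methods

## The model

The aneurysm-specific prediction score is a fixed linear score over three
CTA-derived features of one aneurysm — maximum diameter (mm), location and
shape — originally fitted with component-wise gradient boosting with linear
base learners in a separate derivation cohort. This package treats the
coefficients as data, not as parameters to estimate: the defaults are the
published values (size 0.0427 per mm; location 0 for AcomA/AA, −0.0104
PcomA, −0.1831 posterior circulation, −0.4055 MCA, −0.5973 ICA; +0.5387 for
irregular shape), frozen by tests, and a YAML/JSON override file supports
recalibration experiments without touching code.

The identification rule is a hard within-patient argmax: among one
patient's aneurysms, the one with the largest score is predicted to be the
ruptured one. No probabilistic ranking is produced. Two structurally
different families of competitor rules are evaluated alongside it:

* **argmax rules** (`score_largest`, `diameter_largest`) predict exactly
  one aneurysm per patient (absent ties), so their "predicted" column
  totals the number of patients;
* **membership rules** (`shape_irregular`, `location_is`) flag every
  aneurysm with the feature, independent of patient structure, so their
  totals are aneurysm counts. The published comparison table is consistent
  only with this mixed reading (its diameter row totals 134 = patients,
  its location rows total aneurysm counts such as 101 for PcomA), and the
  implementation follows it. The merged `AcomA+AA` location target exists
  only at evaluation time; the data model keeps the two labels distinct
  because only the coefficient merges them.

### Ties

The published scores are all distinct within patients and ties are never
discussed. Argmax ties are therefore surfaced explicitly: with the default
`tie_policy="flag_all"` every maximal aneurysm is predicted and the patient
is tie-flagged; `"flag_none"` predicts none. A tied ruptured aneurysm
counts as identified only if it is in the predicted set. Ties are exact
floating-point equalities; no tolerance is applied.

## Metrics

All metrics are aneurysm-level percentages from the 2×2 table of rupture
status versus predicted flag: SEN = 100·tp/(tp+fn), SPE = 100·tn/(fp+tn),
DA = 100·(tp+tn)/total. The quantities labelled β ("false omission rate")
and α ("diagnostic error rate") in the source tables are implemented as
100−SEN and 100−SPE: that complement reading is the only one consistent
with every printed row (e.g. the diameter rule's β of 18.7 = 100·25/134).
The textbook false-omission rate fn/(fn+tn) is exposed separately as
`ConfusionCounts.textbook_false_omission_rate` so the nonstandard naming
cannot mislead. Metrics are kept at full precision and rounded to one
decimal only for display.

Two known printing inconsistencies in the source tables are *not*
reproduced: the diameter row's specificity prints as 83.9 where
100·131/156 rounds to 84.0 (with α 16.1 vs 16.0), and the
posterior-circulation row's diagnostic accuracy prints as 51.4 where
100·151/290 rounds to 52.1. The package reports the arithmetic values; the
prose description of the shape rule in the source, which is internally
scrambled, is ignored in favour of its table.

## ROC / AUC

The AUC is computed as the tie-corrected concordance probability (a
ruptured/unruptured pair counts 1 if the ruptured feature value is larger,
½ on a tie), which equals the area under the trapezoidal ROC curve; the
test suite verifies that identity to 1e−12 against a brute-force pairwise
enumeration. The default 95% CI is DeLong's midrank-placement interval,
with a seeded stratified percentile bootstrap (2000 resamples) as the
alternative; the p-value for AUC = 0.5 uses the normal approximation with
the corresponding standard error. The original analysis was run in SPSS
with an unnamed CI method, so small CI discrepancies are expected and
tolerated. The shape feature enters ROC as the 0/1 irregularity indicator,
as in the published AUC table; AUC is invariant under the monotone map to
the 0/0.5387 score component, and a test asserts exactly that.

## Group comparison and agreement

`cohort_summary` reproduces the morphology-table layout: mean ± SD
diameter and score per rupture group compared with a normality-gated test
(Shapiro–Wilk at 0.05 on each group selects Student's t versus
Mann–Whitney U; the gate level is configurable because the original
normality check is unstated), and shape/location rows compared with
chi-squared tests without continuity correction (the SPSS default for
these tables; configurable). `cohens_kappa` wraps the standard Cohen's
kappa for two raters' categorical calls; perfect observed agreement
returns 1.0 including the degenerate single-category case.

## Synthetic cohorts

The generator's defaults are the study conditions: 134 patients; 115/16/3
patients with 2/3/4 aneurysms (assigned by largest-remainder apportionment
in the default deterministic mode, giving exactly 290 aneurysms; sampled
counts are available by flag); exactly one ruptured aneurysm per patient at
a uniformly random position; irregular-shape probabilities 0.709 (ruptured)
and 0.231 (unruptured); location frequencies per rupture group over the
five reported location groups, with draws from the merged anterior group
split evenly between AcomA and AA because separate frequencies are not
reported.

Diameters are drawn by rejection sampling from a normal confined to the
observed 1.8–20.7 mm range. The reported group moments (7.88 ± 3.02 mm
ruptured, 5.02 ± 2.44 mm unruptured) describe diameters already inside
that range, so the underlying normal's (μ, σ) are solved numerically so
that the *truncated* law has exactly the reported mean and SD — naive
rejection from N(7.88, 3.02) would inflate the realized ruptured mean by
≈0.16 mm (and the unruptured mean by ≈0.45 mm) because the cut lower tail
is the heavier one. A truncated normal rather than, say, a lognormal is
used because only mean, SD and range are reported, nothing about skew.
Diameters are rounded to 0.1 mm as a CTA caliper would report them.
Configurations whose size range excludes the target mean ± 6 SD are
rejected as infeasible.

Shape and location are sampled independently given rupture status; only
marginals are reported, so no dependence structure is assumed. This is a
known limitation: real cohorts correlate size, shape and site, so passing
tests on synthetic cohorts demonstrate the pipeline's arithmetic and the
score's behaviour under the reported marginals, not its clinical
performance on new data. The generator also does not simulate
between-reader measurement error (only consensus values are modelled) or
hemorrhage patterns.

Randomness: one global integer seed; each patient consumes an independent
substream spawned deterministically from `(seed, patient_index)`, so
cohorts are bit-reproducible and patient *i*'s draws do not change when
`n_patients` grows.

`generate_from_counts` inverts a confusion-count quadruple into a minimal
cohort on which a given rule reproduces those counts exactly (for argmax
rules this requires fp = fn, one wrong prediction per misidentified
patient, and an unruptured total of one to three per patient). It exists
as a fixture factory: the published diagnostic-accuracy rows can be turned
into cohorts and re-evaluated end-to-end, which is how the metric cells
are verified without the unpublished per-aneurysm supplementary data. It
takes one rule and its counts; a simultaneous multi-rule construction is
generally infeasible and is not attempted.

## Problem sizes and numerical choices

The packaged fixture (17 patients / 38 aneurysms) exercises every pipeline
stage exactly. Property suites run at deliberately small scale — cohorts of
10–25 patients for the AUC/concordance and invariant checks, 1,000 seeded
draws at 15 patients for the generator-invariant sweep, and a single
5,000-patient draw for parameter recovery (within 3 standard errors of the
target mean and irregular fraction) — sizes chosen so the whole suite runs
in seconds while keeping the statistical assertions sharp. Scores are kept
at full double precision internally and printed to 5 decimals, matching
the published precision; score-reproduction tests use an absolute
tolerance of 5×10⁻⁶.

## Limitations

* The full-cohort AUCs and the morphology-table p-values of the source
  study depend on its per-aneurysm supplementary data, which are not
  printed; they can be recomputed by this package only when that file (or
  any cohort CSV) is supplied.
* The score's coefficients are taken as given; no refitting, calibration
  assessment, or comparison with other scoring systems (e.g. PHASES or
  UIATS) is implemented.
* Imaging is out of scope: diameters, shapes and locations arrive as
  already-measured tabular values.
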
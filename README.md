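# cdspd

Clinical decision support tooling for the International Parkinson and
Movement Disorder Society (MDS) clinical diagnostic criteria for
Parkinson's disease — for movement-disorders researchers and informaticians
who need the criteria applied systematically, reproducibly and with an
audit trail, rather than by hand from the paper form.

## What it does

The MDS criteria comprise 24 Boolean criteria in four categories plus a
classification algorithm:

* **Essential criterion** (E1): parkinsonism — bradykinesia in combination
  with rigidity and/or rest tremor, assessed per body region and side on
  0–4 motor-exam items. A prerequisite: without it the criteria are not
  applicable.
* **Absolute exclusion criteria** (AE1–AE9): findings that rule PD out
  outright (e.g. unequivocal cerebellar abnormalities, a normal presynaptic
  dopaminergic scan).
* **Red flags** (RF1–RF10): features counting against PD that must be
  counterbalanced by supportive criteria (e.g. RF4, inspiratory respiratory
  dysfunction: inspiratory stridor or frequent inspiratory sighs).
* **Supportive criteria** (S1–S4): positive features (dramatic dopaminergic
  response, levodopa-induced dyskinesia, documented rest tremor of a limb,
  olfactory loss or cardiac MIBG denervation).

With essential criterion met, zero exclusions, counts `r` red flags and `s`
supportive criteria, the algorithm assigns

* **Clinically Established PD** iff `r = 0` and `s ≥ 2`;
* **Clinically Probable PD** iff `r ≤ 2` and `s ≥ r` (counterbalancing:
  1 red flag needs ≥ 1 supportive, 2 need ≥ 2);
* **Not PD** otherwise, or on any exclusion, or when parkinsonism is absent.

The package provides:

* a structured, schema-validated patient record (12 sections, tri-state
  findings — present / absent / unknown; unknown is never treated as
  absent, it blocks classification until resolved);
* the 24-criterion Boolean engine with per-criterion component traces and
  explicit refusal on missing inputs;
* the three-level classifier with an explainable decision path;
* TD / PIGD / indeterminate motor subtyping from MDS-UPDRS items
  (ratio of mean tremor to mean gait/postural item scores; TD ≥ 1.15,
  PIGD ≤ 0.90);
* a synthetic-cohort generator that inverts the criteria engine: request
  any 24-Boolean profile and get a complete, valid record that evaluates
  back to it exactly;
* validation statistics: per-site and pooled platform-vs-clinician
  concordance with the plain Wilson score interval, and pooled
  (sample-size-weighted) cohort summaries.

## Worked example

Generate the seeded two-site validation cohort (43 records) and classify
one of the discordant cases:

```sh
cdspd synthesize --replication-fixture --out cohort/
cdspd classify cohort/VAL-0012.json --explain
```

```
Diagnostic level: Clinically Probable PD
Criterion counts: 0 absolute exclusion(s), 1 red flag(s), 2 supportive criterion/criteria.
Decision path:
  [ESSENTIAL_PRESENT] parkinsonism present: criteria applicable
  [NO_EXCLUSIONS] no absolute exclusion criterion present
  [COUNTERBALANCED] 1 red flag(s) counterbalanced by 2 supportive criteria (>= 1) -> Clinically Probable PD
Criteria met, with contributing evidence:
  E1 (Parkinsonism (bradykinesia with rigidity and/or rest tremor)): exam.cardinal_signs[bradykinesia,upper_limb,right]; exam.cardinal_signs[rigidity,upper_limb,right]
  RF4 (Inspiratory respiratory dysfunction: diurnal or nocturnal inspiratory stridor or frequent inspiratory sighs): non_motor_symptoms.inspiratory_stridor
  S1 (Clear and dramatic beneficial response to dopaminergic therapy): health_profile.findings.dramatic_dopaminergic_response
  S2 (Presence of levodopa-induced dyskinesia): motor_symptoms.levodopa_induced_dyskinesia
```

This patient meets the established-PD pattern except that inspiratory
stridor is documented — one red flag, counterbalanced by two supportive
criteria, hence Clinically Probable rather than Clinically Established PD.
That is exactly the mechanism behind the discordant cases in the validation
cohort: on paper review a clinician can overlook a rare documented symptom
that a rule engine cannot.

The same pipeline from the library:

```python
from cdspd import classify_record, concordance_report, replicate_validation_fixture

triples = replicate_validation_fixture()
pairs = [(classify_record(rec).level.value, clinician, site)
         for rec, clinician, site in triples]
report = concordance_report(pairs)
print(report.rate, report.ci_low, report.ci_high)   # 93.02 81.4 97.6
```

Other commands: `cdspd validate` (data-quality report, nonzero exit when
invalid), `cdspd criteria` (24-row criterion table with evidence),
`cdspd subtype`, `cdspd evaluate --pairs` (concordance report from a label
table), `cdspd summarize --cohort`, `cdspd dictionary` (the finding codes
and the criteria that read them; also in `docs/data_dictionary.md`).

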
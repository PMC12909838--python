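# Methods

## The diagnostic model

The package implements the MDS clinical diagnostic criteria for Parkinson's
disease as a deterministic Boolean rule system. Each of the 24 criteria is
a small logic tree over coded clinical findings, the cardinal-sign motor
exam, the medication list and disease duration; the classifier then maps
the criterion profile to one of three certainty levels. Nothing is fitted
or probabilistic: given the same record and configuration the output is
identical, and every decision is traceable to named field paths.

Criterion identifiers are stable: `E1` (essential), `AE1`–`AE9` (absolute
exclusions), `RF1`–`RF10` (red flags, with `RF4` fixed to inspiratory
respiratory dysfunction), `S1`–`S4` (supportive). The classifier consumes
only the essential Boolean and the three category counts; the
counterbalancing thresholds (1 red flag → ≥ 1 supportive, 2 → ≥ 2, > 2 →
Not PD) live in a data table (`COUNTERBALANCE_TABLE`) so a criteria
revision can swap them without touching code. "Presence of 2 positive
features" for Clinically Established PD is read as *at least* two: more
supportive evidence cannot disqualify a diagnosis.

When the essential criterion fails, the result is Not PD with a distinct
`criteria_not_applicable` flag and an `ESSENTIAL_ABSENT` rationale code, so
callers can distinguish "excluded" from "the criteria do not apply".

## Three-valued evaluation and refusal

Findings are tri-state (present / absent / unknown); evaluation uses Kleene
logic. A criterion resolves as soon as its value is determined — one
present disjunct resolves a disjunctive criterion even if its sibling is
unrecorded — and otherwise reports the unresolved field paths. A record
with any unresolved criterion is refused outright
(`MissingDataError` with the full missing-field list); the engine never
emits a partial profile. `missing_inputs_for_criteria` is the union of the
evaluators' unresolved inputs, which makes "empty missing list ⟺
classification proceeds" hold by construction. The mandatory-field set of
the validator is likewise derived from what the criteria actually read,
plus core demographics (age, sex, onset year, assessment date).

## Conventions that were genuinely open

* **Essential criterion wording.** The conventional definition is
  conjunctive: bradykinesia *and* at least one of rigidity or rest tremor.
  A literal reading of the platform's published pseudocode ("bradykinesia
  must be present with or without rigidity or rest tremor") makes
  bradykinesia alone sufficient. Both are implemented behind
  `EngineConfig.essential_mode` (`"standard"`, the default, vs
  `"literal_paper"`); the discrepancy is surfaced, not silently resolved.
* **Cardinal-sign presence.** A sign is present iff any assessed body
  region/side scores ≥ 1 (0 is "normal" on the 0–4 item convention), absent
  only when every recorded assessment is a known 0, unresolved otherwise.
  Laterality applies to limbs only; the aggregation is an OR over the
  assessed grid.
* **Time windows.** Criterion time windows are closed intervals
  `[0, w]` years from motor onset — a finding appearing exactly at the
  bound counts. A present windowed finding without an onset time is
  unresolved and flagged `needs_confirmation` by the validator.
* **AE1 and hypermetric saccades.** AE1 is true on any cerebellar
  component; when it is true *solely* through hypermetric saccades the
  result carries a confirmation note, since hypermetric saccades can occur
  in advanced PD and complicate the cerebellar attribution.
* **Subtype thresholds.** TD/PIGD subtyping uses the published MDS-UPDRS
  ratio scheme: tremor = mean of 11 items (2.10, 3.15a/b, 3.16a/b,
  3.17a–e, 3.18), PIGD = mean of 5 items (2.12, 2.13, 3.10, 3.11, 3.12);
  TD iff ratio ≥ 1.15, PIGD iff ratio ≤ 0.90, indeterminate between. With
  PIGD mean 0, any tremor is TD and zero tremor is indeterminate. Item
  lists and thresholds are configuration (`SubtypeConfig`).
* **Shared versus distinct finding codes.** Clinically related inputs read
  by different criteria are deliberately distinct codes where the criteria
  mean different things: symptomatic hyposmia (read negated by RF8) versus
  olfactory loss documented by formal testing (S4); the UPSIT total itself
  is a scale value no criterion reads. This keeps criteria evidentially
  independent and makes every 24-Boolean profile logically satisfiable.
* **Rounding.** Concordance rates are percentages rounded half-up to 2
  decimals; Wilson bounds to 1 decimal. The Wilson interval is the plain
  (uncorrected) form with the normal critical value computed from the
  confidence level. Sensitivity/specificity are deliberately not computed:
  a single-arm concordance design without negative controls cannot support
  them.

## The synthetic cohort generator

The generator is the package's inverse problem: every criterion has a
paired make-true / make-false recipe writing finding, exam and medication
assignments into a conflict-checked store; a record is built from the 24
recipes, demographics and scales are sampled, and the result is verified by
re-evaluating the criteria (any discrepancy or assignment conflict raises
`UnsatisfiableProfileError` — never a silent best-effort record) and by the
default validation ruleset.

What it emulates: the two-site established-disease study structure — sites
of 23 and 20 patients; site age means 70.57 and 75.90 years; sex (7/16 and
4/16 female/male) and ethnicity (22 and 19 not Hispanic or Latino) counts
pinned exactly; MOCA, UPSIT and MDS-UPDRS part totals sampled around the
sites' means (items drawn per-item from binomial(4, p) with p matched to
the part mean); disease duration uniform on 5–15 years (established
disease); every patient on levodopa. The replication fixture additionally
pins the discordance mechanism: exactly three records (two at the first
site, one at the second) carry documented inspiratory stridor while the
clinician label remains Clinically Established PD, so the engine — which
cannot overlook a documented finding — classifies them Clinically Probable
PD. Because that structure is fixed by design, the concordance rates
computed from the fixture (21/23, 19/20, 40/43) are invariant to the seed;
the seed varies the surrounding records.

What it does not emulate: correlations between scale scores and criterion
findings (a record's MDS-UPDRS part-III items are sampled independently of
its cardinal-sign grid), longitudinal trajectories, free-text clinical
notes, and the clinical co-occurrence structure of findings. Passing
round-trip tests therefore demonstrates the engine's logical correctness on
structurally valid records, not performance on real clinical data — the
fixture reproduces the study's arithmetic, not its patients.

## Numerical and testing notes

Problem sizes: the classifier is verified exhaustively against a
brute-force count-space oracle over all 2 × 10 × 11 × 5 = 1100
(essential, exclusion-count, red-flag-count, supportive-count)
combinations; generator round trips run 200 random profiles; Wilson
empirical coverage uses 20 000 seeded binomial replicates at p = 0.9,
n = 43 (the study's pooled size), with the per-count intervals memoised so
the simulation is O(n) interval evaluations. The Wilson implementation is
cross-checked in tests against statsmodels' `proportion_confint`
(`method="wilson"`), which is never used as the implementation.

Records serialize to canonical JSON (sorted keys, deterministic list
orders), so equality of records can be checked on bytes and fixtures are
reproducible bit-for-bit under a fixed seed.

## Known limitations

* Criterion component decompositions are as fine as the published criteria
  require but no finer; some composite clinical judgements (e.g. "dose and
  time-course consistent with drug-induced parkinsonism") remain single
  clinician-asserted findings.
* The validator ships a small default set of cross-field consistency rules
  (each disengageable); it is an extensible ruleset, not an exhaustive
  clinical QA system.
* Only the three-level classification of established PD is implemented; no
  early-PD criteria, no atypical-parkinsonism differential, no
  probabilistic tiers.
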
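"""Data-quality validation of patient records.

The validator applies the platform's three classes of entry checks — data
type, range and presence — plus an extensible set of cross-field
consistency rules. Violations are data, not exceptions: the report lists
every violated rule with its field path so entry staff can resolve them.

Rules are registered in a :class:`RuleSet`; every rule is on by default and
individually disengageable by id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Optional

from . import criteria, vocab
from .record import PatientRecord

RuleKind = Literal["data_type", "range", "presence", "consistency", "needs_confirmation"]


@dataclass(frozen=True)
class Violation:
    field_path: str
    rule: RuleKind
    message: str
    rule_id: str = ""


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def by_rule(self, rule: RuleKind) -> list[Violation]:
        return [v for v in self.violations if v.rule == rule]


RuleFn = Callable[[PatientRecord], Iterator[Violation]]


@dataclass
class RuleSet:
    """An ordered collection of named validation rules."""

    rules: dict[str, RuleFn] = field(default_factory=dict)
    disabled: set[str] = field(default_factory=set)

    def register(self, rule_id: str, fn: RuleFn) -> None:
        self.rules[rule_id] = fn

    def disable(self, rule_id: str) -> None:
        if rule_id not in self.rules:
            raise KeyError(f"unknown rule: {rule_id}")
        self.disabled.add(rule_id)

    def enable(self, rule_id: str) -> None:
        self.disabled.discard(rule_id)

    def active(self) -> list[tuple[str, RuleFn]]:
        return [(rid, fn) for rid, fn in self.rules.items() if rid not in self.disabled]


# ---------------------------------------------------------------------------
# Built-in rules
# ---------------------------------------------------------------------------

def _rule_scale_ranges(record: PatientRecord) -> Iterator[Violation]:
    lo, hi = vocab.ITEM_RANGE
    for part, codes in vocab.ITEMS_BY_PART.items():
        items = getattr(record.scales.updrs, f"{part}_items")
        for code in codes:
            v = items.get(code)
            if v is not None and not lo <= v <= hi:
                yield Violation(
                    f"scales.updrs.{part}_items[{code}]", "range",
                    f"MDS-UPDRS item {code} must be in {lo}-{hi}, got {v}",
                    "scale_ranges",
                )
    if record.scales.moca_total is not None and not (
        vocab.MOCA_RANGE[0] <= record.scales.moca_total <= vocab.MOCA_RANGE[1]
    ):
        yield Violation("scales.moca_total", "range",
                        f"MOCA total must be in 0-30, got {record.scales.moca_total}",
                        "scale_ranges")
    if record.scales.upsit_total is not None and not (
        vocab.UPSIT_RANGE[0] <= record.scales.upsit_total <= vocab.UPSIT_RANGE[1]
    ):
        yield Violation("scales.upsit_total", "range",
                        f"UPSIT total must be in 0-40, got {record.scales.upsit_total}",
                        "scale_ranges")


def _rule_cardinal_score_range(record: PatientRecord) -> Iterator[Violation]:
    for a in record.exam.cardinal_signs:
        if a.score is not None and not 0 <= a.score <= 4:
            yield Violation(
                f"exam.cardinal_signs[{a.sign},{a.body_region},{a.side}].score",
                "range", f"cardinal sign score must be in 0-4, got {a.score}",
                "cardinal_score_range",
            )


def _rule_age_range(record: PatientRecord) -> Iterator[Violation]:
    age = record.demographics.age
    if age is not None and not 0 <= age <= 120:
        yield Violation("demographics.age", "range",
                        f"age must be in 0-120 years, got {age}", "age_range")


def _rule_known_finding_codes(record: PatientRecord) -> Iterator[Violation]:
    for section in vocab.FINDING_SECTIONS:
        obj = getattr(record, section)
        mapping = obj.findings if hasattr(obj, "findings") else obj
        for code in mapping:
            if code not in vocab.FINDINGS:
                yield Violation(f"{section}.{code}", "data_type",
                                f"unknown finding code {code!r} in section {section}",
                                "known_finding_codes")
            elif vocab.FINDINGS[code].section != section:
                yield Violation(
                    f"{section}.{code}", "data_type",
                    f"finding {code!r} belongs in section {vocab.FINDINGS[code].section}",
                    "known_finding_codes")


def _rule_mandatory_demographics(record: PatientRecord) -> Iterator[Violation]:
    for name in ("age", "sex"):
        if getattr(record.demographics, name) is None:
            yield Violation(f"demographics.{name}", "presence",
                            f"mandatory field demographics.{name} is missing",
                            "mandatory_demographics")
    if record.disease_onset_year is None:
        yield Violation("disease_onset_year", "presence",
                        "mandatory field disease_onset_year is missing",
                        "mandatory_demographics")
    if record.assessment_date is None:
        yield Violation("assessment_date", "presence",
                        "mandatory field assessment_date is missing",
                        "mandatory_demographics")


def _rule_criterion_inputs_present(record: PatientRecord) -> Iterator[Violation]:
    # the default mandatory set beyond demographics: everything a criterion reads
    for path in criteria.required_field_paths(record):
        if path.endswith(".years_from_onset"):
            continue  # reported by the timing consistency rule instead
        yield Violation(path, "presence",
                        f"field {path} is required by a diagnostic criterion but unresolved",
                        "criterion_inputs_present")


def _rule_onset_before_assessment(record: PatientRecord) -> Iterator[Violation]:
    dur = record.disease_duration
    if dur is not None and dur < 0:
        yield Violation("disease_onset_year", "consistency",
                        "disease onset year is after the assessment date",
                        "onset_before_assessment")


def _rule_windowed_findings_timed(record: PatientRecord) -> Iterator[Violation]:
    # a present, time-windowed finding without onset timing is ambiguous and
    # needs confirmation before the criteria can run
    for code, d in vocab.FINDINGS.items():
        if d.window_years is None:
            continue
        f = record.finding(code)
        if f is not None and f.present is True and f.years_from_onset is None:
            yield Violation(
                vocab.finding_path(code) + ".years_from_onset", "needs_confirmation",
                f"time-windowed finding {code} is present but its onset time is "
                "not recorded; confirm before classification", "windowed_findings_timed",
            )


def _rule_event_times_within_duration(record: PatientRecord) -> Iterator[Violation]:
    dur = record.disease_duration
    if dur is None:
        return
    for code in vocab.FINDINGS:
        f = record.finding(code)
        if f is not None and f.years_from_onset is not None and f.years_from_onset > dur:
            yield Violation(
                vocab.finding_path(code) + ".years_from_onset", "consistency",
                f"finding {code} is recorded {f.years_from_onset:g} years after onset "
                f"but disease duration is only {dur:g} years",
                "event_times_within_duration",
            )


def _rule_rest_tremor_agreement(record: PatientRecord) -> Iterator[Violation]:
    # an examined rest tremor contradicts a history explicitly denying rest tremor
    exam_present = any(
        a.sign == "rest_tremor" and a.score is not None and a.score >= 1
        for a in record.exam.cardinal_signs
    )
    f = record.finding("rest_tremor_history")
    if exam_present and f is not None and f.present is False:
        yield Violation(
            "motor_symptoms.rest_tremor_history", "consistency",
            "rest tremor scored >= 1 on examination but the rest-tremor history "
            "flag is recorded as absent", "rest_tremor_agreement",
        )


def _rule_dyskinesia_requires_levodopa(record: PatientRecord) -> Iterator[Violation]:
    f = record.finding("levodopa_induced_dyskinesia")
    if f is not None and f.present is True:
        if not any(m.drug_class == "levodopa" for m in record.medications):
            yield Violation(
                "motor_symptoms.levodopa_induced_dyskinesia", "consistency",
                "levodopa-induced dyskinesia recorded but no levodopa medication listed",
                "dyskinesia_requires_levodopa",
            )


def default_ruleset() -> RuleSet:
    rs = RuleSet()
    rs.register("known_finding_codes", _rule_known_finding_codes)
    rs.register("scale_ranges", _rule_scale_ranges)
    rs.register("cardinal_score_range", _rule_cardinal_score_range)
    rs.register("age_range", _rule_age_range)
    rs.register("mandatory_demographics", _rule_mandatory_demographics)
    rs.register("criterion_inputs_present", _rule_criterion_inputs_present)
    rs.register("onset_before_assessment", _rule_onset_before_assessment)
    rs.register("windowed_findings_timed", _rule_windowed_findings_timed)
    rs.register("event_times_within_duration", _rule_event_times_within_duration)
    rs.register("rest_tremor_agreement", _rule_rest_tremor_agreement)
    rs.register("dyskinesia_requires_levodopa", _rule_dyskinesia_requires_levodopa)
    return rs


def validate_record(record: PatientRecord,
                    ruleset: Optional[RuleSet] = None) -> ValidationReport:
    """Apply the (active) validation rules to a parsed record.

    Deterministic for a fixed record and ruleset; violations are sorted by
    field path then rule id.
    """
    rs = ruleset if ruleset is not None else default_ruleset()
    violations: list[Violation] = []
    for _, fn in rs.active():
        violations.extend(fn(record))
    violations.sort(key=lambda v: (v.field_path, v.rule_id, v.message))
    return ValidationReport(violations=tuple(violations))


def missing_inputs_for_criteria(record: PatientRecord) -> list[str]:
    """Field paths required by at least one diagnostic criterion but unresolved.

    An empty list means classification may proceed (:func:`evaluate_all`
    will not refuse this record).
    """
    return criteria.required_field_paths(record)
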
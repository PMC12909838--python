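"""Structured patient records for parkinsonian diagnostic evaluation.

A :class:`PatientRecord` mirrors the data-entry workflow of a movement
disorders assessment: twelve named sections (demographics through
diagnostics) holding demographic fields, coded tri-state clinical findings,
medications, the cardinal-sign motor exam and rating-scale totals.

Clinical findings are tri-state: ``present`` is ``True`` (examined and
found), ``False`` (examined and absent) or ``None`` (not recorded). A
finding absent from a section's mapping is equivalent to ``present=None``.
Unknown is never coerced to absent — the criteria engine refuses to run on
unresolved inputs rather than guessing.

Records serialize to canonical JSON: sorted keys, two-space indent,
deterministically ordered assessment and medication lists, so semantically
equal records produce byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import vocab


class RecordError(Exception):
    """Base class for record parsing/schema problems."""


class RecordParseError(RecordError):
    """Raised when a record stream is not syntactically well-formed."""


class RecordSchemaError(RecordError):
    """Raised when a well-formed stream does not match the record schema."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TemporalFinding(_Model):
    """One coded clinical finding with optional onset-relative timing.

    ``years_from_onset`` is the time (years, >= 0) at which the finding
    first appeared relative to motor onset; it is meaningful only when the
    finding is present.
    """

    present: Optional[bool] = None
    years_from_onset: Optional[float] = None

    @model_validator(mode="after")
    def _timing_only_when_present(self) -> "TemporalFinding":
        if self.present is not True and self.years_from_onset is not None:
            raise ValueError(
                "years_from_onset may only be set on a finding recorded as present"
            )
        if self.years_from_onset is not None and self.years_from_onset < 0:
            raise ValueError("years_from_onset must be >= 0")
        return self


class Demographics(_Model):
    age: Optional[float] = None
    sex: Optional[Literal["female", "male"]] = None
    ethnicity: Optional[Literal["hispanic_or_latino", "not_hispanic_or_latino",
                                "unknown"]] = None


class CardinalSignAssessment(_Model):
    """One cardinal motor sign scored on one body region and side.

    Scores follow the 0-4 motor-exam item convention; a sign is counted
    present on an assessment iff its score is >= 1. Laterality applies to
    limbs only, so ``side`` is ``not_applicable`` exactly when the region is
    the neck.
    """

    sign: Literal["bradykinesia", "rigidity", "rest_tremor"]
    body_region: Literal["upper_limb", "lower_limb", "neck"]
    side: Literal["right", "left", "not_applicable"]
    score: Optional[int] = None

    @model_validator(mode="after")
    def _laterality(self) -> "CardinalSignAssessment":
        if (self.body_region == "neck") != (self.side == "not_applicable"):
            raise ValueError("side must be not_applicable exactly when body_region is neck")
        return self


class MDSUPDRS(_Model):
    """MDS-UPDRS parts I-IV as mappings of canonical item code to 0-4 score.

    Item keys must belong to the instrument's canonical item set for the
    part; an item missing from the mapping is unrecorded. Part sums are
    derived over recorded items.
    """

    part1_items: dict[str, Optional[int]] = Field(default_factory=dict)
    part2_items: dict[str, Optional[int]] = Field(default_factory=dict)
    part3_items: dict[str, Optional[int]] = Field(default_factory=dict)
    part4_items: dict[str, Optional[int]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _known_items(self) -> "MDSUPDRS":
        for part, allowed in vocab.ITEMS_BY_PART.items():
            items = getattr(self, f"{part}_items")
            unknown = set(items) - set(allowed)
            if unknown:
                raise ValueError(f"unknown MDS-UPDRS {part} item(s): {sorted(unknown)}")
        return self

    def part_sum(self, part: int) -> Optional[int]:
        items = getattr(self, f"part{part}_items")
        scores = [v for v in items.values() if v is not None]
        return sum(scores) if scores else None

    def item(self, code: str) -> Optional[int]:
        part = code.split(".")[0]
        return getattr(self, f"part{part}_items").get(code)


class Scales(_Model):
    updrs: MDSUPDRS = Field(default_factory=MDSUPDRS)
    moca_total: Optional[int] = None
    upsit_total: Optional[int] = None


class Medication(_Model):
    name: str
    drug_class: Literal[
        "levodopa", "dopamine_agonist", "maob_inhibitor", "comt_inhibitor",
        "amantadine", "anticholinergic", "dopamine_receptor_blocker",
        "dopamine_depleting_agent", "other",
    ] = "other"
    start_year: Optional[int] = None
    stop_year: Optional[int] = None
    response: Literal["marked", "moderate", "minimal", "none", "unknown"] = "unknown"


class FamilyHistory(_Model):
    pd_in_first_degree_relative: Optional[bool] = None
    pd_in_other_relative: Optional[bool] = None
    notes: Optional[str] = None


class SocialEnvironmental(_Model):
    smoking_status: Optional[Literal["never", "former", "current"]] = None
    caffeine_use: Optional[bool] = None
    pesticide_exposure: Optional[bool] = None
    well_water_use: Optional[bool] = None


class OccupationalMilitary(_Model):
    military_service: Optional[bool] = None
    herbicide_exposure: Optional[bool] = None
    occupation: Optional[str] = None


class HealthProfile(_Model):
    findings: dict[str, TemporalFinding] = Field(default_factory=dict)
    comorbidities: list[str] = Field(default_factory=list)


class Exam(_Model):
    cardinal_signs: list[CardinalSignAssessment] = Field(default_factory=list)
    findings: dict[str, TemporalFinding] = Field(default_factory=dict)


class PatientRecord(_Model):
    """The full structured clinical record all diagnostic criteria read."""

    subject_id: str
    site: str = ""
    demographics: Demographics = Field(default_factory=Demographics)
    disease_onset_year: Optional[int] = None
    assessment_date: Optional[_dt.date] = None
    motor_symptoms: dict[str, TemporalFinding] = Field(default_factory=dict)
    non_motor_symptoms: dict[str, TemporalFinding] = Field(default_factory=dict)
    family_history: FamilyHistory = Field(default_factory=FamilyHistory)
    social_environmental: SocialEnvironmental = Field(default_factory=SocialEnvironmental)
    occupational_military: OccupationalMilitary = Field(default_factory=OccupationalMilitary)
    health_profile: HealthProfile = Field(default_factory=HealthProfile)
    medications: list[Medication] = Field(default_factory=list)
    exam: Exam = Field(default_factory=Exam)
    scales: Scales = Field(default_factory=Scales)
    domain_specific: dict[str, str] = Field(default_factory=dict)
    diagnostics: dict[str, TemporalFinding] = Field(default_factory=dict)

    @field_validator("assessment_date", mode="before")
    @classmethod
    def _parse_date(cls, v: Any) -> Any:
        if isinstance(v, str):
            try:
                return _dt.date.fromisoformat(v)
            except ValueError as exc:
                raise ValueError(f"assessment_date must be an ISO 8601 date: {exc}")
        return v

    @property
    def disease_duration(self) -> Optional[float]:
        """Disease duration in years (assessment year minus onset year)."""
        if self.assessment_date is None or self.disease_onset_year is None:
            return None
        return float(self.assessment_date.year - self.disease_onset_year)

    # -- finding access -----------------------------------------------------

    def finding(self, code: str) -> Optional[TemporalFinding]:
        """Look a coded finding up in its home section (None = unrecorded)."""
        d = vocab.FINDINGS[code]
        section = getattr(self, d.section)
        mapping = section.findings if hasattr(section, "findings") else section
        return mapping.get(code)

    def set_finding(self, code: str, present: Optional[bool],
                    years_from_onset: Optional[float] = None) -> None:
        d = vocab.FINDINGS[code]
        section = getattr(self, d.section)
        mapping = section.findings if hasattr(section, "findings") else section
        mapping[code] = TemporalFinding(present=present, years_from_onset=years_from_onset)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _canonical(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, list):
        return [_canonical(v) for v in obj]
    return obj


def write_record(record: PatientRecord) -> str:
    """Serialize a record to its canonical JSON text form.

    Canonicalization sorts object keys and orders the cardinal-sign and
    medication lists deterministically, so two semantically equal records
    produce byte-identical output.
    """
    rec = record.model_copy(deep=True)
    rec.exam.cardinal_signs = sorted(
        rec.exam.cardinal_signs, key=lambda a: (a.sign, a.body_region, a.side)
    )
    rec.medications = sorted(
        rec.medications, key=lambda m: (m.name, m.drug_class, m.start_year or 0)
    )
    data = _canonical(rec.model_dump(mode="json"))
    return json.dumps(data, indent=2, sort_keys=True) + "\n"


def parse_record(stream: Any) -> PatientRecord:
    """Parse a record from JSON text (a string or a readable text stream).

    Unknown values are preserved as unknown, never coerced to absent.
    Malformed JSON raises :class:`RecordParseError` with the offending
    position; a well-formed document that violates the schema (unknown
    section or field, bad type) raises :class:`RecordSchemaError`.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RecordParseError(
            f"malformed record at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict):
        raise RecordSchemaError("a record must be a JSON object")
    try:
        return PatientRecord.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        raise RecordSchemaError(str(exc)) from exc


def read_record_file(path: Any) -> PatientRecord:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_record(fh)


def write_record_file(record: PatientRecord, path: Any) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_record(record))
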
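"""Shared fixtures: hand-built baseline records and the seeded study fixture."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings, HealthCheck

from cdspd import vocab
from cdspd.record import (
    CardinalSignAssessment,
    Demographics,
    Medication,
    PatientRecord,
)
from cdspd.synthetic import replicate_validation_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_GRID = [
    (region, side)
    for region, side in (
        ("upper_limb", "right"), ("upper_limb", "left"),
        ("lower_limb", "right"), ("lower_limb", "left"),
        ("neck", "not_applicable"),
    )
]


def make_baseline(duration: int = 3) -> PatientRecord:
    """A complete record with every criterion input examined and absent.

    All cardinal signs score 0, every coded finding is explicitly absent,
    demographics and scales are filled, and a levodopa medication is
    listed. ``duration`` defaults to under 5 years so the
    nonmotor-absence red flag cannot fire on an otherwise empty record.
    """
    rec = PatientRecord(
        subject_id="BASE-0001",
        site="TEST",
        demographics=Demographics(age=70.0, sex="male",
                                  ethnicity="not_hispanic_or_latino"),
        disease_onset_year=2024 - duration,
        assessment_date=dt.date(2024, 6, 15),
    )
    rec.medications.append(Medication(name="carbidopa-levodopa",
                                      drug_class="levodopa", response="marked"))
    for sign in vocab.CARDINAL_SIGNS:
        for region, side in _GRID:
            rec.exam.cardinal_signs.append(CardinalSignAssessment(
                sign=sign, body_region=region, side=side, score=0))
    # canonical order, so parse(write(rec)) compares equal to rec itself
    rec.exam.cardinal_signs.sort(key=lambda a: (a.sign, a.body_region, a.side))
    for code in vocab.FINDINGS:
        rec.set_finding(code, False)
    for part, codes in vocab.ITEMS_BY_PART.items():
        items = getattr(rec.scales.updrs, f"{part}_items")
        for code in codes:
            items[code] = 0
    rec.scales.moca_total = 26
    rec.scales.upsit_total = 20
    return rec


def set_cardinal(rec: PatientRecord, sign: str, region: str, side: str,
                 score: int) -> None:
    for a in rec.exam.cardinal_signs:
        if (a.sign, a.body_region, a.side) == (sign, region, side):
            a.score = score
            return
    raise KeyError((sign, region, side))


@pytest.fixture()
def baseline() -> PatientRecord:
    return make_baseline()


@pytest.fixture()
def parkinsonian(baseline: PatientRecord) -> PatientRecord:
    """Baseline plus bradykinesia and rigidity: the essential criterion holds."""
    set_cardinal(baseline, "bradykinesia", "upper_limb", "right", 2)
    set_cardinal(baseline, "rigidity", "upper_limb", "right", 1)
    return baseline


@pytest.fixture(scope="session")
def study_fixture():
    """The seeded 43-patient two-site replication fixture (record, label, site)."""
    return replicate_validation_fixture()
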
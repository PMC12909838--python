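"""Synthetic cohort generation: round trips, determinism, the study fixture."""

import dataclasses

import numpy as np
import pytest

from cdspd.classify import DiagnosticLevel, classify_record
from cdspd.criteria import evaluate_all
from cdspd.record import write_record
from cdspd.stats import concordance_report
from cdspd.synthetic import (
    STUDY_SITES,
    CohortSpec,
    CohortSpecError,
    SiteSpec,
    UnsatisfiableProfileError,
    _Assignments,
    established_profile,
    random_profile,
    replicate_validation_fixture,
    stridor_probable_profile,
    synthesize_cohort,
    synthesize_patient,
)
from cdspd.validation import validate_record


class TestSynthesizePatient:
    def test_essential_only_round_trips(self):
        target = dataclasses.replace(established_profile(2),
                                     supportive=(False,) * 4)
        rec = synthesize_patient(target, seed=0)
        assert evaluate_all(rec) == target

    def test_stridor_probable_record_classifies_probable(self):
        rec = synthesize_patient(stridor_probable_profile(2), seed=1)
        assert rec.finding("inspiratory_stridor").present is True
        assert classify_record(rec).level is DiagnosticLevel.CLINICALLY_PROBABLE_PD

    def test_random_profiles_round_trip(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            target = random_profile(rng)
            rec = synthesize_patient(target, seed=rng)
            assert evaluate_all(rec) == target

    def test_generated_records_pass_validation(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            rec = synthesize_patient(random_profile(rng), seed=rng)
            assert validate_record(rec).is_valid

    def test_same_seed_same_bytes(self):
        a = synthesize_patient(established_profile(3), seed=99)
        b = synthesize_patient(established_profile(3), seed=99)
        assert write_record(a) == write_record(b)

    def test_conflicting_assignments_are_unsatisfiable(self):
        a = _Assignments()
        a.set_finding("inspiratory_stridor", True)
        with pytest.raises(UnsatisfiableProfileError):
            a.set_finding("inspiratory_stridor", False)
        a.set_cardinal("bradykinesia", "upper_limb", "right", 2)
        with pytest.raises(UnsatisfiableProfileError):
            a.set_cardinal("bradykinesia", "upper_limb", "right", 0)


class TestSynthesizeCohort:
    def _spec(self, seed=0):
        return CohortSpec(
            sites=tuple(dataclasses.replace(s) for s in STUDY_SITES),
            profile_mix=((established_profile(2), 0.6),
                         (stridor_probable_profile(2), 0.4)),
            seed=seed,
        )

    def test_site_counts_exact(self):
        cohort = synthesize_cohort(self._spec())
        assert len(cohort) == 43
        sites = [rec.site for rec, _ in cohort]
        assert sites.count("UVMMC") == 23
        assert sites.count("OHSU/VAPORHCS") == 20

    def test_same_seed_identical_cohorts(self):
        a = synthesize_cohort(self._spec(seed=5))
        b = synthesize_cohort(self._spec(seed=5))
        assert [(write_record(r), lab) for r, lab in a] == \
            [(write_record(r), lab) for r, lab in b]

    def test_different_seeds_differ_but_counts_match(self):
        a = synthesize_cohort(self._spec(seed=1))
        b = synthesize_cohort(self._spec(seed=2))
        assert len(a) == len(b) == 43
        assert [write_record(r) for r, _ in a] != [write_record(r) for r, _ in b]

    def test_concordant_rule_matches_platform(self):
        for rec, label in synthesize_cohort(self._spec())[:10]:
            assert classify_record(rec).level.value == label

    def test_invalid_specs_rejected(self):
        spec = self._spec()
        bad_weights = dataclasses.replace(
            spec, profile_mix=((established_profile(2), 0.5),))
        with pytest.raises(CohortSpecError):
            synthesize_cohort(bad_weights)
        bad_n = dataclasses.replace(
            spec, sites=(dataclasses.replace(STUDY_SITES[0], n=0),))
        with pytest.raises(CohortSpecError):
            synthesize_cohort(bad_n)


class TestReplicationFixture:
    def test_shape_and_site_structure(self, study_fixture):
        assert len(study_fixture) == 43
        sites = [site for _, _, site in study_fixture]
        assert sites.count("UVMMC") == 23
        assert sites.count("OHSU/VAPORHCS") == 20

    def test_disagreements_are_exactly_the_stridor_records(self, study_fixture):
        mismatch_sites = []
        for rec, clinician, site in study_fixture:
            platform = classify_record(rec).level.value
            if platform != clinician:
                assert rec.finding("inspiratory_stridor").present is True
                assert platform == "Clinically Probable PD"
                assert clinician == "Clinically Established PD"
                mismatch_sites.append(site)
            else:
                assert rec.finding("inspiratory_stridor").present is False
        assert sorted(mismatch_sites) == ["OHSU/VAPORHCS", "UVMMC", "UVMMC"]

    def test_per_site_concordant_counts(self, study_fixture):
        pairs = [(classify_record(rec).level.value, clinician, site)
                 for rec, clinician, site in study_fixture]
        report = concordance_report(pairs)
        by_site = {s.site: s for s in report.per_site}
        assert (by_site["UVMMC"].n_concordant, by_site["UVMMC"].n) == (21, 23)
        assert (by_site["OHSU/VAPORHCS"].n_concordant,
                by_site["OHSU/VAPORHCS"].n) == (19, 20)

    def test_fixture_is_deterministic(self, study_fixture):
        again = replicate_validation_fixture()
        assert [(write_record(r), lab, s) for r, lab, s in study_fixture] == \
            [(write_record(r), lab, s) for r, lab, s in again]

    def test_demographic_counts_pinned(self, study_fixture):
        by_site = {}
        for rec, _, site in study_fixture:
            by_site.setdefault(site, []).append(rec)
        a, b = by_site["UVMMC"], by_site["OHSU/VAPORHCS"]
        assert sum(r.demographics.sex == "female" for r in a) == 7
        assert sum(r.demographics.sex == "female" for r in b) == 4
        assert sum(r.demographics.ethnicity == "not_hispanic_or_latino"
                   for r in a) == 22
        assert sum(r.demographics.ethnicity == "not_hispanic_or_latino"
                   for r in b) == 19

    def test_established_disease_throughout(self, study_fixture):
        assert all(rec.disease_duration >= 5 for rec, _, _ in study_fixture)
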
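"""Three-level classification: examples, exhaustive count-space oracle,
monotonicity and record-level composition."""

import itertools

import pytest

from cdspd.classify import (
    DiagnosticLevel,
    classify,
    classify_record,
    explain,
)
from cdspd.criteria import CriteriaProfile, MissingDataError, evaluate_all

from conftest import make_baseline, set_cardinal

EST = DiagnosticLevel.CLINICALLY_ESTABLISHED_PD
PROB = DiagnosticLevel.CLINICALLY_PROBABLE_PD
NOT = DiagnosticLevel.NOT_PD


def profile_from_counts(essential: bool, n_ex: int, n_rf: int,
                        n_sup: int) -> CriteriaProfile:
    return CriteriaProfile(
        essential=essential,
        exclusions=tuple(i < n_ex for i in range(9)),
        red_flags=tuple(i < n_rf for i in range(10)),
        supportive=tuple(i < n_sup for i in range(4)),
    )


def oracle_level(essential: bool, n_ex: int, n_rf: int, n_sup: int) -> DiagnosticLevel:
    """Independent transcription of the published classification algorithm."""
    if not essential or n_ex > 0:
        return NOT
    if n_rf == 0 and n_sup >= 2:
        return EST
    if n_rf > 2:
        return NOT
    return PROB if n_sup >= n_rf else NOT


ALL_COUNTS = list(itertools.product([True, False], range(10), range(11), range(5)))


class TestExamples:
    def test_established_needs_two_positive_and_zero_negative_features(self):
        assert classify(profile_from_counts(True, 0, 0, 2)).level is EST

    def test_one_red_flag_with_support_is_probable(self):
        # the study's mismatch mechanism: one red flag (inspiratory stridor)
        rf4_only = CriteriaProfile(
            essential=True, exclusions=(False,) * 9,
            red_flags=tuple(i == 3 for i in range(10)),
            supportive=(True, False, False, False),
        )
        assert classify(rf4_only).level is PROB

    def test_any_exclusion_rules_pd_out_regardless_of_support(self):
        for n_sup in range(5):
            assert classify(profile_from_counts(True, 1, 0, n_sup)).level is NOT

    def test_red_flag_cap_at_two(self):
        assert classify(profile_from_counts(True, 0, 3, 4)).level is NOT

    def test_essential_absent_flags_criteria_not_applicable(self):
        result = classify(profile_from_counts(False, 0, 0, 4))
        assert result.level is NOT
        assert result.criteria_not_applicable is True
        assert result.rationale[0].rule_id == "ESSENTIAL_ABSENT"

    def test_zero_red_flags_few_supportive_is_probable(self):
        assert classify(profile_from_counts(True, 0, 0, 0)).level is PROB
        assert classify(profile_from_counts(True, 0, 0, 1)).level is PROB


class TestCountSpace:
    def test_exhaustive_equivalence_with_count_oracle(self):
        # 2 x 10 x 11 x 5 = 1100 count combinations
        for essential, n_ex, n_rf, n_sup in ALL_COUNTS:
            got = classify(profile_from_counts(essential, n_ex, n_rf, n_sup))
            assert got.level is oracle_level(essential, n_ex, n_rf, n_sup), \
                (essential, n_ex, n_rf, n_sup)

    def test_level_depends_only_on_counts(self):
        # same counts realized by different criterion subsets -> same level
        a = CriteriaProfile(True, (False,) * 9,
                            (True, False, True) + (False,) * 7,
                            (True, True, False, False))
        b = CriteriaProfile(True, (False,) * 9,
                            (False,) * 8 + (True, True),
                            (False, False, True, True))
        assert classify(a).level is classify(b).level

    def test_monotone_in_negative_and_positive_features(self):
        for essential, n_ex, n_rf, n_sup in ALL_COUNTS:
            base = classify(profile_from_counts(essential, n_ex, n_rf, n_sup)).level
            if n_ex < 9:
                worse = classify(profile_from_counts(essential, n_ex + 1, n_rf, n_sup))
                assert worse.level.rank <= base.rank
            if n_rf < 10:
                worse = classify(profile_from_counts(essential, n_ex, n_rf + 1, n_sup))
                assert worse.level.rank <= base.rank
            if n_sup < 4:
                better = classify(profile_from_counts(essential, n_ex, n_rf, n_sup + 1))
                assert better.level.rank >= base.rank

    def test_totality_every_profile_gets_exactly_one_level(self):
        levels = {classify(profile_from_counts(*c)).level for c in ALL_COUNTS}
        assert levels == {EST, PROB, NOT}


class TestRecordLevel:
    def _established_record(self):
        rec = make_baseline(duration=8)
        rec.set_finding("sleep_dysfunction", True)
        set_cardinal(rec, "bradykinesia", "upper_limb", "right", 2)
        set_cardinal(rec, "rigidity", "upper_limb", "right", 1)
        rec.set_finding("dramatic_dopaminergic_response", True)
        rec.set_finding("olfactory_loss_documented", True)
        return rec

    def test_textbook_established_record(self):
        result = classify_record(self._established_record())
        assert result.level is EST

    def test_stridor_downgrades_to_probable(self):
        rec = self._established_record()
        rec.set_finding("inspiratory_stridor", True)
        result = classify_record(rec)
        assert result.level is PROB
        assert result.counts == (0, 1, 2)

    def test_classify_record_composes_engine_and_classifier(self):
        rec = self._established_record()
        assert classify_record(rec).level is classify(evaluate_all(rec)).level

    def test_incomplete_record_is_refused_with_field_list(self):
        rec = self._established_record()
        del rec.non_motor_symptoms["inspiratory_stridor"]
        with pytest.raises(MissingDataError) as err:
            classify_record(rec)
        assert any("inspiratory_stridor" in f for f in err.value.missing_fields)


class TestExplain:
    def test_established_report_cites_counts_and_rules(self):
        rec = TestRecordLevel()._established_record()
        text = explain(classify_record(rec))
        assert "Clinically Established PD" in text
        assert "0 red flag" in text and "ESTABLISHED" in text

    def test_probable_report_names_the_red_flag(self):
        rec = TestRecordLevel()._established_record()
        rec.set_finding("inspiratory_stridor", True)
        text = explain(classify_record(rec))
        assert "Clinically Probable PD" in text
        assert "RF4" in text and "inspiratory_stridor" in text

    def test_not_pd_report_names_the_exclusion(self):
        rec = TestRecordLevel()._established_record()
        rec.set_finding("cerebellar_gait", True)
        text = explain(classify_record(rec))
        assert "Not PD" in text and "AE1" in text
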
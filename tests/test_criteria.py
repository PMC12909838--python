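"""The 24-criterion Boolean engine: category logic, time windows, refusal."""

import pytest

from cdspd import vocab
from cdspd.criteria import (
    CRITERION_IDS,
    CriteriaProfile,
    EngineConfig,
    MissingDataError,
    evaluate_absolute_exclusions,
    evaluate_all,
    evaluate_detailed,
    evaluate_essential,
    evaluate_red_flags,
    evaluate_supportive,
)

from conftest import make_baseline, set_cardinal

STANDARD = EngineConfig(essential_mode="standard")
LITERAL = EngineConfig(essential_mode="literal_paper")


class TestEssential:
    def test_bradykinesia_alone_splits_the_two_modes(self):
        rec = make_baseline()
        set_cardinal(rec, "bradykinesia", "upper_limb", "right", 2)
        assert evaluate_essential(rec, LITERAL).value is True
        assert evaluate_essential(rec, STANDARD).value is False

    def test_bradykinesia_with_rigidity_true_in_both_modes(self, parkinsonian):
        assert evaluate_essential(parkinsonian, STANDARD).value is True
        assert evaluate_essential(parkinsonian, LITERAL).value is True

    def test_rest_tremor_without_bradykinesia_false_in_both_modes(self):
        rec = make_baseline()
        set_cardinal(rec, "rest_tremor", "upper_limb", "left", 3)
        rec.set_finding("rest_tremor_history", True)  # keep record consistent
        assert evaluate_essential(rec, STANDARD).value is False
        assert evaluate_essential(rec, LITERAL).value is False

    def test_any_region_or_side_counts(self):
        rec = make_baseline()
        set_cardinal(rec, "bradykinesia", "lower_limb", "left", 1)
        set_cardinal(rec, "rigidity", "neck", "not_applicable", 2)
        assert evaluate_essential(rec, STANDARD).value is True

    def test_components_cover_all_three_cardinal_signs(self, parkinsonian):
        result = evaluate_essential(parkinsonian)
        names = {c.name.split("_present")[0] for c in result.components}
        assert names == {"bradykinesia", "rigidity", "rest_tremor"}


class TestExclusions:
    def test_all_absent_gives_nine_false(self, baseline):
        results = evaluate_absolute_exclusions(baseline)
        assert [r.criterion_id for r in results] == [f"AE{i}" for i in range(1, 10)]
        assert all(r.value is False for r in results)

    def test_cerebellar_gait_triggers_ae1(self, baseline):
        baseline.set_finding("cerebellar_gait", True)
        ae1 = evaluate_absolute_exclusions(baseline)[0]
        assert ae1.value is True and ae1.note is None

    def test_isolated_hypermetric_saccades_true_but_flagged(self, baseline):
        baseline.set_finding("hypermetric_saccades", True)
        ae1 = evaluate_absolute_exclusions(baseline)[0]
        assert ae1.value is True
        assert ae1.note is not None and "confirmation" in ae1.note

    def test_ae1_component_set_includes_oculomotor_findings(self, baseline):
        ae1 = evaluate_absolute_exclusions(baseline)[0]
        names = {c.name for c in ae1.components}
        assert {"cerebellar_gait", "limb_ataxia", "gaze_evoked_nystagmus",
                "macro_square_wave_jerks", "hypermetric_saccades"} <= names

    def test_drug_induced_parkinsonism_needs_exposure_and_course(self, baseline):
        from cdspd.record import Medication
        baseline.set_finding("drug_induced_course_consistent", True)
        assert evaluate_absolute_exclusions(baseline)[4].value is False  # no exposure
        baseline.medications.append(
            Medication(name="risperidone", drug_class="dopamine_receptor_blocker"))
        assert evaluate_absolute_exclusions(baseline)[4].value is True

    def test_levodopa_nonresponse_requires_moderate_severity(self, baseline):
        baseline.set_finding("levodopa_observable_response", False)
        assert evaluate_absolute_exclusions(baseline)[5].value is False
        baseline.set_finding("disease_severity_at_least_moderate", True)
        assert evaluate_absolute_exclusions(baseline)[5].value is True


class TestRedFlags:
    def test_all_absent_gives_ten_false(self, baseline):
        results = evaluate_red_flags(baseline)
        assert [r.criterion_id for r in results] == [f"RF{i}" for i in range(1, 11)]
        assert all(r.value is False for r in results)

    @pytest.mark.parametrize("code", ["inspiratory_stridor", "frequent_inspiratory_sigh"])
    def test_rf4_is_a_disjunction(self, baseline, code):
        baseline.set_finding(code, True)
        assert evaluate_red_flags(baseline)[3].value is True

    def test_time_window_is_closed_at_the_bound(self):
        rec = make_baseline(duration=8)
        rec.set_finding("regular_wheelchair_use", True, years_from_onset=5.0)
        assert evaluate_red_flags(rec)[0].value is True  # exactly at 5 years counts
        rec.set_finding("regular_wheelchair_use", True, years_from_onset=5.5)
        assert evaluate_red_flags(rec)[0].value is False

    def test_windowed_finding_without_timing_is_unresolved(self, baseline):
        baseline.set_finding("recurrent_falls_from_balance", True)
        rf6 = evaluate_red_flags(baseline)[5]
        assert rf6.value is None
        assert any("years_from_onset" in m for m in rf6.missing_fields)

    def test_nonmotor_absence_red_flag_needs_established_disease(self):
        short = make_baseline(duration=3)
        assert evaluate_red_flags(short)[7].value is False
        established = make_baseline(duration=6)
        assert evaluate_red_flags(established)[7].value is True
        established.set_finding("sleep_dysfunction", True)
        assert evaluate_red_flags(established)[7].value is False


class TestSupportive:
    def test_all_absent_gives_four_false(self, baseline):
        results = evaluate_supportive(baseline)
        assert [r.criterion_id for r in results] == ["S1", "S2", "S3", "S4"]
        assert all(r.value is False for r in results)

    def test_dramatic_response_satisfies_exactly_s1(self, baseline):
        baseline.set_finding("dramatic_dopaminergic_response", True)
        values = [r.value for r in evaluate_supportive(baseline)]
        assert values == [True, False, False, False]

    def test_rest_tremor_supportive_from_history_or_exam(self, baseline):
        assert evaluate_supportive(baseline)[2].value is False
        baseline.set_finding("rest_tremor_history", True)
        assert evaluate_supportive(baseline)[2].value is True
        baseline.set_finding("rest_tremor_history", False)
        set_cardinal(baseline, "rest_tremor", "lower_limb", "right", 1)
        # exam finding alone suffices, but contradicts the denied history
        baseline.set_finding("rest_tremor_history", None)
        assert evaluate_supportive(baseline)[2].value is True


class TestEvaluateAll:
    def test_parkinsonism_only_record(self, parkinsonian):
        profile = evaluate_all(parkinsonian)
        assert profile.essential is True
        assert profile.n_exclusions == 0
        assert profile.n_red_flags == 0
        assert profile.n_supportive == 0

    def test_refusal_names_the_unknown_field(self, parkinsonian):
        del parkinsonian.exam.findings["cerebellar_gait"]
        with pytest.raises(MissingDataError) as err:
            evaluate_all(parkinsonian)
        assert any("cerebellar_gait" in f for f in err.value.missing_fields)

    def test_never_a_partial_profile(self, parkinsonian):
        del parkinsonian.diagnostics["dat_scan_normal"]
        results = evaluate_detailed(parkinsonian)
        assert sum(r.value is None for r in results) == 1
        with pytest.raises(MissingDataError):
            evaluate_all(parkinsonian)

    def test_profile_cardinalities_fixed(self, parkinsonian):
        profile = evaluate_all(parkinsonian)
        assert (len(profile.exclusions), len(profile.red_flags),
                len(profile.supportive)) == (9, 10, 4)
        with pytest.raises(ValueError):
            CriteriaProfile(essential=True, exclusions=(False,) * 8,
                            red_flags=(False,) * 10, supportive=(False,) * 4)

    def test_determinism(self, parkinsonian):
        assert evaluate_all(parkinsonian) == evaluate_all(parkinsonian)

    def test_criterion_ids_stable(self):
        assert CRITERION_IDS == ("E1",) + tuple(f"AE{i}" for i in range(1, 10)) \
            + tuple(f"RF{i}" for i in range(1, 11)) + tuple(f"S{i}" for i in range(1, 5))


_RF_TRIGGERS = {
    "RF1": ("regular_wheelchair_use", 4.0),
    "RF2": ("no_motor_progression_over_5y", None),
    "RF3": ("severe_dysphagia", 2.0),
    "RF4": ("inspiratory_stridor", None),
    "RF5": ("severe_orthostatic_hypotension", 3.0),
    "RF6": ("recurrent_falls_from_balance", 1.0),
    "RF7": ("disproportionate_anterocollis", 4.0),
    "RF9": ("pyramidal_tract_signs", None),
    "RF10": ("bilateral_symmetric_parkinsonism", None),
}


class TestProperties:
    @pytest.mark.parametrize("rf_id", sorted(_RF_TRIGGERS))
    def test_adding_one_red_flag_flips_no_other_criterion(self, rf_id):
        rec = make_baseline(duration=8)
        rec.set_finding("sleep_dysfunction", True)  # keep RF8 off at 8 years
        before = evaluate_all(rec).as_dict()
        code, years = _RF_TRIGGERS[rf_id]
        rec.set_finding(code, True, years_from_onset=years)
        after = evaluate_all(rec).as_dict()
        changed = {k for k in before if before[k] != after[k]}
        assert changed == {rf_id}

    def test_trace_names_contributing_fields_for_true_criteria(self):
        rec = make_baseline(duration=8)
        rec.set_finding("sleep_dysfunction", True)
        set_cardinal(rec, "bradykinesia", "upper_limb", "right", 2)
        set_cardinal(rec, "rigidity", "upper_limb", "right", 1)
        rec.set_finding("inspiratory_stridor", True)
        rec.set_finding("olfactory_loss_documented", True)
        for r in evaluate_detailed(rec):
            if r.value is True:
                evidence = [f for c in r.components if c.value for f in c.fields]
                assert evidence, f"{r.criterion_id} has no contributing fields"

    def test_every_finding_code_read_by_some_criterion_or_section(self):
        from cdspd.criteria import CRITERIA
        read = {code for c in CRITERIA for code in c.finding_codes}
        assert read == set(vocab.FINDINGS)
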
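"""Controlled vocabulary for clinical findings and MDS-UPDRS items.

Every clinical finding a diagnostic criterion can read is registered here
with the record section it lives in and, where the criterion is
time-windowed, the closed upper bound (in years from motor onset) within
which the finding counts. The criteria engine, the record validator and the
synthetic generator all key off this registry, so the finding codes double
as the package's data dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Record sections, in the order the data-entry workflow presents them.
SECTIONS: tuple[str, ...] = (
    "demographics",
    "motor_symptoms",
    "non_motor_symptoms",
    "family_history",
    "social_environmental",
    "occupational_military",
    "health_profile",
    "medications",
    "exam",
    "scales",
    "domain_specific",
    "diagnostics",
)

#: Sections that hold coded tri-state findings.
FINDING_SECTIONS: tuple[str, ...] = (
    "motor_symptoms",
    "non_motor_symptoms",
    "health_profile",
    "exam",
    "diagnostics",
)


@dataclass(frozen=True)
class FindingDef:
    """Definition of one coded clinical finding.

    ``window_years`` is the closed onset-relative time bound a criterion
    applies to the finding (``None`` when the criterion is not
    time-windowed). A finding recorded as present exactly at the bound
    counts as within the window.
    """

    code: str
    section: str
    label: str
    window_years: float | None = None


def _f(code: str, section: str, label: str, window: float | None = None) -> FindingDef:
    return FindingDef(code=code, section=section, label=label, window_years=window)


_FINDING_DEFS: tuple[FindingDef, ...] = (
    # --- exam: neurological findings ---
    _f("cerebellar_gait", "exam", "Unequivocal cerebellar gait abnormality"),
    _f("limb_ataxia", "exam", "Limb ataxia"),
    _f("gaze_evoked_nystagmus", "exam", "Sustained gaze-evoked nystagmus"),
    _f("macro_square_wave_jerks", "exam", "Macro square wave jerks"),
    _f("hypermetric_saccades", "exam", "Hypermetric saccades"),
    _f("downgaze_palsy", "exam", "Downward vertical supranuclear gaze palsy"),
    _f("downward_saccade_slowing", "exam",
       "Selective slowing of downward vertical saccades"),
    _f("cortical_sensory_loss", "exam",
       "Unequivocal cortical sensory loss (graphesthesia/stereognosis, primary modalities intact)"),
    _f("limb_ideomotor_apraxia", "exam", "Clear limb ideomotor apraxia"),
    _f("progressive_aphasia", "exam", "Progressive aphasia on examination"),
    _f("pyramidal_tract_signs", "exam",
       "Otherwise unexplained pyramidal tract signs (pyramidal weakness or clear pathologic hyperreflexia)"),
    _f("disproportionate_anterocollis", "exam",
       "Disproportionate (dystonic) anterocollis", 10.0),
    _f("hand_or_foot_contractures", "exam", "Contractures of hand or feet", 10.0),
    # --- health profile: diagnoses, treatment course, severity ---
    _f("bvftd_diagnosis", "health_profile",
       "Diagnosis of probable behavioural-variant frontotemporal dementia", 5.0),
    _f("primary_progressive_aphasia_diagnosis", "health_profile",
       "Diagnosis of primary progressive aphasia", 5.0),
    _f("lower_limb_restricted_parkinsonism_over_3y", "health_profile",
       "Parkinsonian features restricted to the lower limbs for more than 3 years"),
    _f("drug_induced_course_consistent", "health_profile",
       "Dose and time-course of dopamine-blocking treatment consistent with drug-induced parkinsonism"),
    _f("disease_severity_at_least_moderate", "health_profile",
       "Disease of at least moderate severity"),
    _f("levodopa_observable_response", "health_profile",
       "Observable response to high-dose levodopa therapy"),
    _f("alternative_condition_documented", "health_profile",
       "Documented alternative condition producing parkinsonism, plausibly connected to the symptoms"),
    _f("dramatic_dopaminergic_response", "health_profile",
       "Clear and dramatic beneficial response to dopaminergic therapy"),
    # --- motor symptoms ---
    _f("regular_wheelchair_use", "motor_symptoms",
       "Rapid progression of gait impairment requiring regular wheelchair use", 5.0),
    _f("no_motor_progression_over_5y", "motor_symptoms",
       "Complete absence of progression of motor symptoms or signs over 5 or more years (not treatment-related)"),
    _f("bilateral_symmetric_parkinsonism", "motor_symptoms",
       "Bilateral symmetric parkinsonism throughout the disease course"),
    _f("marked_motor_fluctuations", "motor_symptoms",
       "Marked on/off motor fluctuations, including predictable end-of-dose wearing-off"),
    _f("levodopa_induced_dyskinesia", "motor_symptoms", "Levodopa-induced dyskinesia"),
    _f("rest_tremor_history", "motor_symptoms",
       "Rest tremor of a limb, documented past or current"),
    # --- non-motor symptoms ---
    _f("severe_dysphonia_or_dysarthria", "non_motor_symptoms",
       "Severe dysphonia or dysarthria (speech unintelligible most of the time)", 5.0),
    _f("severe_dysphagia", "non_motor_symptoms",
       "Severe dysphagia (requiring soft food, NG tube or gastrostomy feeding)", 5.0),
    _f("inspiratory_stridor", "non_motor_symptoms",
       "Diurnal or nocturnal inspiratory stridor"),
    _f("frequent_inspiratory_sigh", "non_motor_symptoms", "Frequent inspiratory sighs"),
    _f("severe_orthostatic_hypotension", "non_motor_symptoms",
       "Severe orthostatic hypotension (>=30 mmHg systolic / >=15 mmHg diastolic within 3 min of standing)", 5.0),
    _f("severe_urinary_dysfunction", "non_motor_symptoms",
       "Severe urinary retention or incontinence (not simply functional)", 5.0),
    _f("recurrent_falls_from_balance", "non_motor_symptoms",
       "Recurrent (>1/year) falls because of impaired balance", 3.0),
    _f("sleep_dysfunction", "non_motor_symptoms",
       "Sleep dysfunction (sleep-maintenance insomnia, excessive daytime somnolence, REM sleep behaviour disorder symptoms)"),
    _f("autonomic_dysfunction_symptoms", "non_motor_symptoms",
       "Autonomic dysfunction (constipation, daytime urinary urgency, symptomatic orthostasis)"),
    _f("hyposmia_symptom", "non_motor_symptoms", "Subjective or reported hyposmia"),
    _f("psychiatric_dysfunction", "non_motor_symptoms",
       "Psychiatric dysfunction (depression, anxiety or hallucinations)"),
    # --- diagnostics: test results ---
    _f("dat_scan_normal", "diagnostics",
       "Normal functional neuroimaging of the presynaptic dopaminergic system"),
    _f("olfactory_loss_documented", "diagnostics",
       "Olfactory loss documented by formal testing"),
    _f("mibg_cardiac_denervation", "diagnostics",
       "Cardiac sympathetic denervation on MIBG scintigraphy"),
)

FINDINGS: dict[str, FindingDef] = {d.code: d for d in _FINDING_DEFS}

#: Finding codes grouped by the section they are recorded in.
FINDINGS_BY_SECTION: dict[str, tuple[str, ...]] = {
    section: tuple(d.code for d in _FINDING_DEFS if d.section == section)
    for section in FINDING_SECTIONS
}


def finding_path(code: str) -> str:
    """Dotted field path of a finding inside a patient record."""
    d = FINDINGS[code]
    if d.section in ("exam", "health_profile"):
        return f"{d.section}.findings.{code}"
    return f"{d.section}.{code}"


# ---------------------------------------------------------------------------
# MDS-UPDRS item codes (parts I-IV, every item scored 0-4)
# ---------------------------------------------------------------------------

PART1_ITEMS: tuple[str, ...] = tuple(f"1.{i}" for i in range(1, 14))
PART2_ITEMS: tuple[str, ...] = tuple(f"2.{i}" for i in range(1, 14))
PART3_ITEMS: tuple[str, ...] = (
    "3.1", "3.2",
    "3.3a", "3.3b", "3.3c", "3.3d", "3.3e",          # rigidity: neck, RUE, LUE, RLE, LLE
    "3.4a", "3.4b", "3.5a", "3.5b", "3.6a", "3.6b",  # finger taps, hand movements, pron/sup
    "3.7a", "3.7b", "3.8a", "3.8b",                  # toe taps, leg agility
    "3.9", "3.10", "3.11", "3.12", "3.13", "3.14",
    "3.15a", "3.15b", "3.16a", "3.16b",              # postural / kinetic tremor
    "3.17a", "3.17b", "3.17c", "3.17d", "3.17e",     # rest tremor amplitude
    "3.18",                                          # constancy of rest tremor
)
PART4_ITEMS: tuple[str, ...] = tuple(f"4.{i}" for i in range(1, 7))

ITEMS_BY_PART: dict[str, tuple[str, ...]] = {
    "part1": PART1_ITEMS,
    "part2": PART2_ITEMS,
    "part3": PART3_ITEMS,
    "part4": PART4_ITEMS,
}

# Cardinal motor signs and the exam grid they are assessed on.
CARDINAL_SIGNS: tuple[str, ...] = ("bradykinesia", "rigidity", "rest_tremor")
BODY_REGIONS: tuple[str, ...] = ("upper_limb", "lower_limb", "neck")
SIDES: tuple[str, ...] = ("right", "left", "not_applicable")

# Instrument score ranges.
MOCA_RANGE = (0, 30)
UPSIT_RANGE = (0, 40)
ITEM_RANGE = (0, 4)
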
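"""Boolean evaluation of the 24 MDS diagnostic criteria for Parkinson's disease.

The criteria fall into four categories: one essential criterion
(parkinsonism), nine absolute exclusion criteria (AE1-AE9), ten red flags
(RF1-RF10) and four supportive criteria (S1-S4). Each criterion is a small
logic tree over coded clinical findings, the cardinal-sign motor exam, the
medication list and disease duration. Evaluation is three-valued (Kleene):
a criterion resolves to a Boolean as soon as its value is determined by the
recorded inputs, and otherwise reports exactly which field paths are
unresolved. A record with any unresolved criterion input is refused by
:func:`evaluate_all` rather than evaluated partially.

Every result carries a component-level evidence trace naming the field
paths that contributed, so a classification can be explained back to the
recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from . import vocab
from .record import PatientRecord


class MissingDataError(Exception):
    """Refusal to evaluate: required criterion inputs are missing or inconsistent."""

    def __init__(self, missing_fields: Sequence[str]):
        self.missing_fields = sorted(set(missing_fields))
        super().__init__(
            "missing or inconsistent data prevented evaluation; unresolved inputs: "
            + ", ".join(self.missing_fields)
        )


@dataclass(frozen=True)
class EngineConfig:
    """Tunable evaluation conventions.

    essential_mode
        ``"standard"`` (default): parkinsonism requires bradykinesia together
        with at least one of rigidity or rest tremor. ``"literal_paper"``:
        bradykinesia alone suffices, with or without the other two signs —
        both readings of the criterion's wording are preserved rather than
        silently resolved.
    ae1_isolated_saccades_confirm
        When AE1 is true solely through hypermetric saccades the result is
        annotated for confirmation (they can occur in advanced PD).
    """

    essential_mode: Literal["standard", "literal_paper"] = "standard"
    ae1_isolated_saccades_confirm: bool = True


DEFAULT_CONFIG = EngineConfig()


@dataclass(frozen=True)
class ComponentResult:
    """Outcome of one named subcomponent of a criterion's logic."""

    name: str
    value: Optional[bool]
    fields: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()
    note: Optional[str] = None


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str
    category: Literal["essential", "exclusion", "red_flag", "supportive"]
    name: str
    value: Optional[bool]
    components: tuple[ComponentResult, ...]
    missing_fields: tuple[str, ...] = ()
    note: Optional[str] = None


@dataclass(frozen=True)
class CriteriaProfile:
    """The 24 Boolean criterion outcomes (1 essential / 9 exclusions / 10
    red flags / 4 supportive)."""

    essential: bool
    exclusions: tuple[bool, ...]
    red_flags: tuple[bool, ...]
    supportive: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.exclusions) != 9:
            raise ValueError("exactly 9 absolute exclusion outcomes required")
        if len(self.red_flags) != 10:
            raise ValueError("exactly 10 red flag outcomes required")
        if len(self.supportive) != 4:
            raise ValueError("exactly 4 supportive outcomes required")

    @property
    def n_exclusions(self) -> int:
        return sum(self.exclusions)

    @property
    def n_red_flags(self) -> int:
        return sum(self.red_flags)

    @property
    def n_supportive(self) -> int:
        return sum(self.supportive)

    def as_dict(self) -> dict[str, bool]:
        out = {"E1": self.essential}
        out.update({f"AE{i+1}": v for i, v in enumerate(self.exclusions)})
        out.update({f"RF{i+1}": v for i, v in enumerate(self.red_flags)})
        out.update({f"S{i+1}": v for i, v in enumerate(self.supportive)})
        return out

    @classmethod
    def from_dict(cls, values: dict[str, bool]) -> "CriteriaProfile":
        """Build a profile from a {criterion id: Boolean} mapping; ids absent
        from the mapping default to False."""
        unknown = set(values) - set(CRITERION_IDS)
        if unknown:
            raise ValueError(f"unknown criterion id(s): {sorted(unknown)}")
        return cls(
            essential=bool(values.get("E1", False)),
            exclusions=tuple(bool(values.get(f"AE{i}", False)) for i in range(1, 10)),
            red_flags=tuple(bool(values.get(f"RF{i}", False)) for i in range(1, 11)),
            supportive=tuple(bool(values.get(f"S{i}", False)) for i in range(1, 5)),
        )

    @classmethod
    def from_results(cls, results: Sequence[CriterionResult]) -> "CriteriaProfile":
        by_id = {r.criterion_id: r for r in results}
        expected = CRITERION_IDS
        if set(by_id) != set(expected) or len(results) != len(expected):
            raise ValueError("a profile requires exactly the 24 defined criterion results")
        undefined = [r.criterion_id for r in results if r.value is None]
        if undefined:
            raise ValueError(f"criterion value undefined for: {sorted(undefined)}")
        return cls(
            essential=bool(by_id["E1"].value),
            exclusions=tuple(bool(by_id[f"AE{i}"].value) for i in range(1, 10)),
            red_flags=tuple(bool(by_id[f"RF{i}"].value) for i in range(1, 11)),
            supportive=tuple(bool(by_id[f"S{i}"].value) for i in range(1, 5)),
        )


# ---------------------------------------------------------------------------
# Three-valued connectives
# ---------------------------------------------------------------------------

def _k_or(parts: Sequence[ComponentResult]) -> tuple[Optional[bool], tuple[str, ...]]:
    if any(p.value is True for p in parts):
        return True, ()
    if any(p.value is None for p in parts):
        return None, tuple(m for p in parts if p.value is None for m in p.missing)
    return False, ()


def _k_and(parts: Sequence[ComponentResult]) -> tuple[Optional[bool], tuple[str, ...]]:
    if any(p.value is False for p in parts):
        return False, ()
    if any(p.value is None for p in parts):
        return None, tuple(m for p in parts if p.value is None for m in p.missing)
    return True, ()


# ---------------------------------------------------------------------------
# Atomic component evaluators
# ---------------------------------------------------------------------------

def _finding_component(record: PatientRecord, code: str,
                       name: Optional[str] = None,
                       negate: bool = False) -> ComponentResult:
    """Evaluate a coded tri-state finding, applying its time window.

    A time-windowed finding counts only if it appeared within the closed
    interval [0, window] years from motor onset; a present windowed finding
    without a recorded onset time is unresolved (the record is incomplete
    for the criterion, pending confirmation).
    """
    d = vocab.FINDINGS[code]
    path = vocab.finding_path(code)
    f = record.finding(code)
    cname = name or code
    if f is None or f.present is None:
        value: Optional[bool] = None
        missing: tuple[str, ...] = (path,)
    elif f.present is False:
        value, missing = False, ()
    elif d.window_years is None:
        value, missing = True, ()
    elif f.years_from_onset is None:
        value, missing = None, (path + ".years_from_onset",)
    else:
        value, missing = f.years_from_onset <= d.window_years, ()
    if negate and value is not None:
        value = not value
    return ComponentResult(name=cname, value=value, fields=(path,), missing=missing)


def _cardinal_component(record: PatientRecord, sign: str,
                        regions: Optional[tuple[str, ...]] = None) -> ComponentResult:
    """Presence of a cardinal motor sign aggregated over body regions/sides.

    A sign is present if any assessed region/side scores >= 1 (score 0 is
    normal on the 0-4 item convention). It is absent only when every
    recorded assessment of the sign is a known 0; no assessment, or only
    unknown scores, leaves the sign unresolved.
    """
    relevant = [
        a for a in record.exam.cardinal_signs
        if a.sign == sign and (regions is None or a.body_region in regions)
    ]
    fields = tuple(
        f"exam.cardinal_signs[{sign},{a.body_region},{a.side}]" for a in relevant
    )
    scope = "" if regions is None else "_" + "_".join(regions)
    name = f"{sign}{scope}_present"
    if any(a.score is not None and a.score >= 1 for a in relevant):
        pos = tuple(
            f"exam.cardinal_signs[{a.sign},{a.body_region},{a.side}]"
            for a in relevant if a.score is not None and a.score >= 1
        )
        return ComponentResult(name=name, value=True, fields=pos)
    if not relevant:
        return ComponentResult(
            name=name, value=None, fields=(),
            missing=(f"exam.cardinal_signs[{sign}]",),
        )
    unknown = tuple(
        f"exam.cardinal_signs[{a.sign},{a.body_region},{a.side}].score"
        for a in relevant if a.score is None
    )
    if unknown:
        return ComponentResult(name=name, value=None, fields=fields, missing=unknown)
    return ComponentResult(name=name, value=False, fields=fields)


def _med_class_component(record: PatientRecord, classes: tuple[str, ...],
                         name: str) -> ComponentResult:
    hits = tuple(
        f"medications[{i}]" for i, m in enumerate(record.medications)
        if m.drug_class in classes
    )
    return ComponentResult(name=name, value=bool(hits), fields=hits or ("medications",))


def _duration_component(record: PatientRecord, at_least: float) -> ComponentResult:
    dur = record.disease_duration
    if dur is None:
        return ComponentResult(
            name=f"disease_duration_ge_{at_least:g}y", value=None,
            fields=("disease_onset_year", "assessment_date"),
            missing=("disease_onset_year", "assessment_date"),
        )
    return ComponentResult(
        name=f"disease_duration_ge_{at_least:g}y", value=dur >= at_least,
        fields=("disease_onset_year", "assessment_date"),
    )


# ---------------------------------------------------------------------------
# Criterion definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    category: Literal["essential", "exclusion", "red_flag", "supportive"]
    name: str
    #: finding codes the criterion reads (for the data dictionary / schema)
    finding_codes: tuple[str, ...]
    #: non-finding inputs, as human-readable dependency labels
    other_inputs: tuple[str, ...] = ()

    def evaluate(self, record: PatientRecord,
                 config: EngineConfig = DEFAULT_CONFIG) -> CriterionResult:
        components, value, missing, note = _EVALUATORS[self.criterion_id](record, config)
        return CriterionResult(
            criterion_id=self.criterion_id, category=self.category, name=self.name,
            value=value, components=tuple(components),
            missing_fields=tuple(sorted(set(missing))), note=note,
        )


def _eval_or(record: PatientRecord, codes: Sequence[str]):
    comps = [_finding_component(record, c) for c in codes]
    value, missing = _k_or(comps)
    return comps, value, missing, None


def _eval_finding(record: PatientRecord, code: str):
    comp = _finding_component(record, code)
    return [comp], comp.value, comp.missing, None


def _eval_e1(record: PatientRecord, config: EngineConfig):
    brady = _cardinal_component(record, "bradykinesia")
    rigid = _cardinal_component(record, "rigidity")
    tremor = _cardinal_component(record, "rest_tremor")
    comps = [brady, rigid, tremor]
    if config.essential_mode == "literal_paper":
        # bradykinesia must be present, with or without rigidity or rest tremor
        value, missing = brady.value, brady.missing
    else:
        ev, em = _k_or([rigid, tremor])
        either = ComponentResult(
            name="rigidity_or_rest_tremor", value=ev,
            fields=rigid.fields + tremor.fields, missing=em,
        )
        value, missing = _k_and([brady, either])
    return comps, value, missing, None


def _eval_ae1(record: PatientRecord, config: EngineConfig):
    gait = _finding_component(record, "cerebellar_gait")
    ataxia = _finding_component(record, "limb_ataxia")
    oculo = [
        _finding_component(record, "gaze_evoked_nystagmus"),
        _finding_component(record, "macro_square_wave_jerks"),
        _finding_component(record, "hypermetric_saccades"),
    ]
    ov, om = _k_or(oculo)
    oculomotor = ComponentResult(
        name="cerebellar_oculomotor_abnormality", value=ov,
        fields=tuple(f for c in oculo for f in c.fields), missing=om,
    )
    comps = [gait, ataxia] + oculo
    value, missing = _k_or([gait, ataxia, oculomotor])
    note = None
    if (
        config.ae1_isolated_saccades_confirm
        and value is True
        and oculo[2].value is True
        and gait.value is not True and ataxia.value is not True
        and oculo[0].value is not True and oculo[1].value is not True
    ):
        note = (
            "needs_confirmation: AE1 is true solely through hypermetric saccades, "
            "which can be observed in advanced PD"
        )
    return comps, value, missing, note


def _eval_ae5(record: PatientRecord, config: EngineConfig):
    exposure = _med_class_component(
        record, ("dopamine_receptor_blocker", "dopamine_depleting_agent"),
        "dopamine_blocking_or_depleting_treatment",
    )
    course = _finding_component(record, "drug_induced_course_consistent")
    comps = [exposure, course]
    value, missing = _k_and(comps)
    return comps, value, missing, None


def _eval_ae6(record: PatientRecord, config: EngineConfig):
    severity = _finding_component(record, "disease_severity_at_least_moderate")
    no_response = _finding_component(
        record, "levodopa_observable_response",
        name="levodopa_response_absent", negate=True,
    )
    comps = [severity, no_response]
    value, missing = _k_and(comps)
    return comps, value, missing, None


def _eval_rf8(record: PatientRecord, config: EngineConfig):
    dur = _duration_component(record, 5.0)
    absences = [
        _finding_component(record, code, name=f"no_{code}", negate=True)
        for code in ("sleep_dysfunction", "autonomic_dysfunction_symptoms",
                     "hyposmia_symptom", "psychiatric_dysfunction")
    ]
    comps = [dur] + absences
    value, missing = _k_and(comps)
    return comps, value, missing, None


def _eval_s1(record: PatientRecord, config: EngineConfig):
    comps = [
        _finding_component(record, "dramatic_dopaminergic_response"),
        _finding_component(record, "marked_motor_fluctuations"),
    ]
    value, missing = _k_or(comps)
    return comps, value, missing, None


def _eval_s3(record: PatientRecord, config: EngineConfig):
    history = _finding_component(record, "rest_tremor_history")
    exam = _cardinal_component(record, "rest_tremor", regions=("upper_limb", "lower_limb"))
    comps = [history, exam]
    value, missing = _k_or(comps)
    return comps, value, missing, None


def _mk_or_eval(codes: tuple[str, ...]):
    return lambda record, config: _eval_or(record, codes)


def _mk_finding_eval(code: str):
    return lambda record, config: _eval_finding(record, code)


_EVALUATORS = {
    "E1": _eval_e1,
    "AE1": _eval_ae1,
    "AE2": _mk_or_eval(("downgaze_palsy", "downward_saccade_slowing")),
    "AE3": _mk_or_eval(("bvftd_diagnosis", "primary_progressive_aphasia_diagnosis")),
    "AE4": _mk_finding_eval("lower_limb_restricted_parkinsonism_over_3y"),
    "AE5": _eval_ae5,
    "AE6": _eval_ae6,
    "AE7": _mk_or_eval(("cortical_sensory_loss", "limb_ideomotor_apraxia",
                        "progressive_aphasia")),
    "AE8": _mk_finding_eval("dat_scan_normal"),
    "AE9": _mk_finding_eval("alternative_condition_documented"),
    "RF1": _mk_finding_eval("regular_wheelchair_use"),
    "RF2": _mk_finding_eval("no_motor_progression_over_5y"),
    "RF3": _mk_or_eval(("severe_dysphonia_or_dysarthria", "severe_dysphagia")),
    "RF4": _mk_or_eval(("inspiratory_stridor", "frequent_inspiratory_sigh")),
    "RF5": _mk_or_eval(("severe_orthostatic_hypotension", "severe_urinary_dysfunction")),
    "RF6": _mk_finding_eval("recurrent_falls_from_balance"),
    "RF7": _mk_or_eval(("disproportionate_anterocollis", "hand_or_foot_contractures")),
    "RF8": _eval_rf8,
    "RF9": _mk_finding_eval("pyramidal_tract_signs"),
    "RF10": _mk_finding_eval("bilateral_symmetric_parkinsonism"),
    "S1": _eval_s1,
    "S2": _mk_finding_eval("levodopa_induced_dyskinesia"),
    "S3": _eval_s3,
    "S4": _mk_or_eval(("olfactory_loss_documented", "mibg_cardiac_denervation")),
}


def _crit(cid, category, name, codes, other=()):
    return Criterion(criterion_id=cid, category=category, name=name,
                     finding_codes=tuple(codes), other_inputs=tuple(other))


CRITERIA: tuple[Criterion, ...] = (
    _crit("E1", "essential", "Parkinsonism (bradykinesia with rigidity and/or rest tremor)",
          (), other=("exam.cardinal_signs",)),
    _crit("AE1", "exclusion", "Unequivocal cerebellar abnormalities",
          ("cerebellar_gait", "limb_ataxia", "gaze_evoked_nystagmus",
           "macro_square_wave_jerks", "hypermetric_saccades")),
    _crit("AE2", "exclusion", "Downward vertical supranuclear gaze palsy or selective "
          "slowing of downward vertical saccades",
          ("downgaze_palsy", "downward_saccade_slowing")),
    _crit("AE3", "exclusion", "Probable bvFTD or primary progressive aphasia within the "
          "first 5 years of disease",
          ("bvftd_diagnosis", "primary_progressive_aphasia_diagnosis")),
    _crit("AE4", "exclusion", "Parkinsonian features restricted to the lower limbs for "
          "more than 3 years",
          ("lower_limb_restricted_parkinsonism_over_3y",)),
    _crit("AE5", "exclusion", "Dopamine receptor blocker or depleting agent in a dose and "
          "time-course consistent with drug-induced parkinsonism",
          ("drug_induced_course_consistent",), other=("medications",)),
    _crit("AE6", "exclusion", "Absence of observable response to high-dose levodopa "
          "despite at least moderate disease severity",
          ("disease_severity_at_least_moderate", "levodopa_observable_response")),
    _crit("AE7", "exclusion", "Unequivocal cortical sensory loss, clear limb ideomotor "
          "apraxia, or progressive aphasia",
          ("cortical_sensory_loss", "limb_ideomotor_apraxia", "progressive_aphasia")),
    _crit("AE8", "exclusion", "Normal functional neuroimaging of the presynaptic "
          "dopaminergic system",
          ("dat_scan_normal",)),
    _crit("AE9", "exclusion", "Documented alternative condition producing parkinsonism, "
          "plausibly connected to the symptoms",
          ("alternative_condition_documented",)),
    _crit("RF1", "red_flag", "Rapid gait impairment requiring regular wheelchair use "
          "within 5 years of onset",
          ("regular_wheelchair_use",)),
    _crit("RF2", "red_flag", "Complete absence of progression of motor symptoms or signs "
          "over 5 or more years (not treatment-related)",
          ("no_motor_progression_over_5y",)),
    _crit("RF3", "red_flag", "Early severe bulbar dysfunction within the first 5 years",
          ("severe_dysphonia_or_dysarthria", "severe_dysphagia")),
    _crit("RF4", "red_flag", "Inspiratory respiratory dysfunction: diurnal or nocturnal "
          "inspiratory stridor or frequent inspiratory sighs",
          ("inspiratory_stridor", "frequent_inspiratory_sigh")),
    _crit("RF5", "red_flag", "Severe autonomic failure in the first 5 years of disease",
          ("severe_orthostatic_hypotension", "severe_urinary_dysfunction")),
    _crit("RF6", "red_flag", "Recurrent (>1/year) falls because of impaired balance "
          "within 3 years of onset",
          ("recurrent_falls_from_balance",)),
    _crit("RF7", "red_flag", "Disproportionate anterocollis or hand/foot contractures "
          "within the first 10 years",
          ("disproportionate_anterocollis", "hand_or_foot_contractures")),
    _crit("RF8", "red_flag", "Absence of any common nonmotor feature despite 5 years "
          "of disease",
          ("sleep_dysfunction", "autonomic_dysfunction_symptoms", "hyposmia_symptom",
           "psychiatric_dysfunction"),
          other=("disease_onset_year", "assessment_date")),
    _crit("RF9", "red_flag", "Otherwise unexplained pyramidal tract signs",
          ("pyramidal_tract_signs",)),
    _crit("RF10", "red_flag", "Bilateral symmetric parkinsonism throughout the disease "
          "course",
          ("bilateral_symmetric_parkinsonism",)),
    _crit("S1", "supportive", "Clear and dramatic beneficial response to dopaminergic "
          "therapy",
          ("dramatic_dopaminergic_response", "marked_motor_fluctuations")),
    _crit("S2", "supportive", "Presence of levodopa-induced dyskinesia",
          ("levodopa_induced_dyskinesia",)),
    _crit("S3", "supportive", "Rest tremor of a limb, documented past or current",
          ("rest_tremor_history",), other=("exam.cardinal_signs",)),
    _crit("S4", "supportive", "Olfactory loss or cardiac sympathetic denervation on MIBG",
          ("olfactory_loss_documented", "mibg_cardiac_denervation")),
)

CRITERIA_BY_ID: dict[str, Criterion] = {c.criterion_id: c for c in CRITERIA}
CRITERION_IDS: tuple[str, ...] = tuple(c.criterion_id for c in CRITERIA)


# ---------------------------------------------------------------------------
# Category-level and full evaluation
# ---------------------------------------------------------------------------

def evaluate_essential(record: PatientRecord,
                       config: EngineConfig = DEFAULT_CONFIG) -> CriterionResult:
    return CRITERIA_BY_ID["E1"].evaluate(record, config)


def evaluate_absolute_exclusions(record: PatientRecord,
                                 config: EngineConfig = DEFAULT_CONFIG
                                 ) -> list[CriterionResult]:
    return [CRITERIA_BY_ID[f"AE{i}"].evaluate(record, config) for i in range(1, 10)]


def evaluate_red_flags(record: PatientRecord,
                       config: EngineConfig = DEFAULT_CONFIG) -> list[CriterionResult]:
    return [CRITERIA_BY_ID[f"RF{i}"].evaluate(record, config) for i in range(1, 11)]


def evaluate_supportive(record: PatientRecord,
                        config: EngineConfig = DEFAULT_CONFIG) -> list[CriterionResult]:
    return [CRITERIA_BY_ID[f"S{i}"].evaluate(record, config) for i in range(1, 5)]


def evaluate_detailed(record: PatientRecord,
                      config: EngineConfig = DEFAULT_CONFIG) -> list[CriterionResult]:
    """Evaluate all 24 criteria, returning per-criterion results with traces.

    Unlike :func:`evaluate_all` this does not refuse on missing inputs:
    unresolved criteria carry ``value=None`` and their missing field paths.
    """
    return [c.evaluate(record, config) for c in CRITERIA]


def evaluate_all(record: PatientRecord,
                 config: EngineConfig = DEFAULT_CONFIG) -> CriteriaProfile:
    """Evaluate all 24 criteria to a complete Boolean profile.

    Raises :class:`MissingDataError` carrying the full list of unresolved
    field paths if any criterion cannot be resolved — never a partial
    profile.
    """
    results = evaluate_detailed(record, config)
    missing = [m for r in results if r.value is None for m in r.missing_fields]
    if missing:
        raise MissingDataError(missing)
    return CriteriaProfile.from_results(results)


def required_field_paths(record: PatientRecord,
                         config: EngineConfig = DEFAULT_CONFIG) -> list[str]:
    """Unresolved inputs required by at least one criterion on this record.

    Empty exactly when :func:`evaluate_all` will succeed.
    """
    results = evaluate_detailed(record, config)
    return sorted({m for r in results if r.value is None for m in r.missing_fields})
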
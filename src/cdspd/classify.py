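"""Three-level diagnostic classification from a 24-criterion Boolean profile.

The algorithm layers the four criterion categories:

* parkinsonism (the essential criterion) is a prerequisite — without it the
  criteria are not applicable and the output is Not PD;
* any absolute exclusion criterion rules PD out;
* *Clinically Established PD* requires zero red flags and at least two
  supportive criteria;
* *Clinically Probable PD* tolerates up to two red flags provided each is
  counterbalanced by at least as many supportive criteria;
* everything else is *Not PD*.

The counterbalancing thresholds are shipped as a data table
(:data:`COUNTERBALANCE_TABLE`) rather than hard-coded logic so future
criterion revisions can swap the table without touching the classifier.

The classification depends only on the essential Boolean and the three
category counts; the rationale trace records every rule consulted so the
decision can be reconstructed and explained.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .criteria import (
    CriteriaProfile,
    CriterionResult,
    EngineConfig,
    DEFAULT_CONFIG,
    evaluate_detailed,
    evaluate_all,
)
from .record import PatientRecord


class DiagnosticLevel(enum.Enum):
    NOT_PD = "Not PD"
    CLINICALLY_PROBABLE_PD = "Clinically Probable PD"
    CLINICALLY_ESTABLISHED_PD = "Clinically Established PD"

    @property
    def rank(self) -> int:
        return {"Not PD": 0, "Clinically Probable PD": 1,
                "Clinically Established PD": 2}[self.value]


#: Minimum supportive-criterion count required to counterbalance each
#: tolerated red-flag count; red-flag counts absent from the table are
#: incompatible with a PD diagnosis.
COUNTERBALANCE_TABLE: dict[int, int] = {0: 0, 1: 1, 2: 2}

#: Supportive criteria required for Clinically Established PD (with zero
#: negative features).
ESTABLISHED_MIN_SUPPORTIVE = 2


@dataclass(frozen=True)
class RuleFiring:
    rule_id: str
    inputs: dict
    outcome: str


@dataclass(frozen=True)
class DiagnosticResult:
    level: DiagnosticLevel
    rationale: tuple[RuleFiring, ...]
    counts: tuple[int, int, int]  # (n_exclusions, n_red_flags, n_supportive)
    criteria_not_applicable: bool = False
    #: per-criterion evidence, populated when classified from a record
    criterion_results: Optional[tuple[CriterionResult, ...]] = None


def classify(profile: CriteriaProfile) -> DiagnosticResult:
    """Map a complete criteria profile to one of the three certainty levels."""
    n_ex, n_rf, n_sup = profile.n_exclusions, profile.n_red_flags, profile.n_supportive
    counts = (n_ex, n_rf, n_sup)
    trace: list[RuleFiring] = []

    if not profile.essential:
        trace.append(RuleFiring(
            "ESSENTIAL_ABSENT", {"essential": False},
            "parkinsonism absent: diagnostic criteria not applicable -> Not PD"))
        return DiagnosticResult(DiagnosticLevel.NOT_PD, tuple(trace), counts,
                                criteria_not_applicable=True)
    trace.append(RuleFiring("ESSENTIAL_PRESENT", {"essential": True},
                            "parkinsonism present: criteria applicable"))

    if n_ex > 0:
        which = [f"AE{i+1}" for i, v in enumerate(profile.exclusions) if v]
        trace.append(RuleFiring(
            "ABSOLUTE_EXCLUSION", {"exclusions_true": which},
            f"absolute exclusion criteria present ({', '.join(which)}) -> Not PD"))
        return DiagnosticResult(DiagnosticLevel.NOT_PD, tuple(trace), counts)
    trace.append(RuleFiring("NO_EXCLUSIONS", {"n_exclusions": 0},
                            "no absolute exclusion criterion present"))

    if n_rf == 0 and n_sup >= ESTABLISHED_MIN_SUPPORTIVE:
        trace.append(RuleFiring(
            "ESTABLISHED", {"n_red_flags": 0, "n_supportive": n_sup},
            f"zero negative features and {n_sup} supportive criteria (>= "
            f"{ESTABLISHED_MIN_SUPPORTIVE}) -> Clinically Established PD"))
        return DiagnosticResult(DiagnosticLevel.CLINICALLY_ESTABLISHED_PD,
                                tuple(trace), counts)

    required = COUNTERBALANCE_TABLE.get(n_rf)
    if required is None:
        trace.append(RuleFiring(
            "RED_FLAG_CAP", {"n_red_flags": n_rf},
            f"more than {max(COUNTERBALANCE_TABLE)} red flags cannot be "
            "counterbalanced -> Not PD"))
        return DiagnosticResult(DiagnosticLevel.NOT_PD, tuple(trace), counts)
    if n_sup >= required:
        trace.append(RuleFiring(
            "COUNTERBALANCED", {"n_red_flags": n_rf, "n_supportive": n_sup,
                                "required_supportive": required},
            f"{n_rf} red flag(s) counterbalanced by {n_sup} supportive "
            f"criteria (>= {required}) -> Clinically Probable PD"))
        return DiagnosticResult(DiagnosticLevel.CLINICALLY_PROBABLE_PD,
                                tuple(trace), counts)
    trace.append(RuleFiring(
        "NOT_COUNTERBALANCED", {"n_red_flags": n_rf, "n_supportive": n_sup,
                                "required_supportive": required},
        f"{n_rf} red flag(s) require >= {required} supportive criteria but "
        f"only {n_sup} present -> Not PD"))
    return DiagnosticResult(DiagnosticLevel.NOT_PD, tuple(trace), counts)


def classify_record(record: PatientRecord,
                    config: EngineConfig = DEFAULT_CONFIG) -> DiagnosticResult:
    """Evaluate a record's criteria and classify it in one step.

    Propagates the engine's refusal (:class:`~cdspd.criteria.MissingDataError`)
    when required criterion inputs are unresolved.
    """
    profile = evaluate_all(record, config)  # raises MissingDataError on gaps
    result = classify(profile)
    details = tuple(evaluate_detailed(record, config))
    return DiagnosticResult(
        level=result.level, rationale=result.rationale, counts=result.counts,
        criteria_not_applicable=result.criteria_not_applicable,
        criterion_results=details,
    )


def explain(result: DiagnosticResult) -> str:
    """Render a human-readable report of the decision path."""
    n_ex, n_rf, n_sup = result.counts
    lines = [
        f"Diagnostic level: {result.level.value}",
        f"Criterion counts: {n_ex} absolute exclusion(s), {n_rf} red flag(s), "
        f"{n_sup} supportive criterion/criteria.",
    ]
    if result.criteria_not_applicable:
        lines.append("The essential criterion (parkinsonism) is absent; the "
                     "diagnostic criteria are not applicable to this record.")
    lines.append("Decision path:")
    for firing in result.rationale:
        lines.append(f"  [{firing.rule_id}] {firing.outcome}")
    if result.criterion_results is not None:
        true_crits = [r for r in result.criterion_results if r.value]
        if true_crits:
            lines.append("Criteria met, with contributing evidence:")
            for r in true_crits:
                ev = sorted({f for c in r.components if c.value for f in c.fields})
                lines.append(f"  {r.criterion_id} ({r.name}): " + "; ".join(ev))
    return "\n".join(lines)
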
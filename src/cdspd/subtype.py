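"""Motor subtype classification (TD / PIGD / indeterminate) from MDS-UPDRS items.

The subtype is the ratio of the mean tremor item score to the mean
postural-instability-and-gait-difficulty (PIGD) item score, following the
published MDS-UPDRS ratio scheme: tremor-dominant when the ratio is at
least 1.15, PIGD when it is at most 0.90, indeterminate between. With no
PIGD involvement the ratio is undefined: any tremor then classifies as TD,
and a patient with neither tremor nor PIGD items scored above zero is
indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .record import MDSUPDRS


class MissingItemError(Exception):
    """A configured subtype item is not recorded on the scale."""

    def __init__(self, items: list[str]):
        self.items = sorted(items)
        super().__init__("missing MDS-UPDRS item(s) required for subtype "
                         "classification: " + ", ".join(self.items))


#: Tremor items: patient-reported tremor, postural and kinetic tremor of the
#: hands, rest tremor amplitude at the five sites, and rest tremor constancy.
TREMOR_ITEMS: tuple[str, ...] = (
    "2.10", "3.15a", "3.15b", "3.16a", "3.16b",
    "3.17a", "3.17b", "3.17c", "3.17d", "3.17e", "3.18",
)

#: PIGD items: walking/balance and freezing by report, gait, freezing of
#: gait and postural stability on examination.
PIGD_ITEMS: tuple[str, ...] = ("2.12", "2.13", "3.10", "3.11", "3.12")


@dataclass(frozen=True)
class SubtypeConfig:
    tremor_items: tuple[str, ...] = TREMOR_ITEMS
    pigd_items: tuple[str, ...] = PIGD_ITEMS
    td_threshold: float = 1.15     # label TD when ratio >= this
    pigd_threshold: float = 0.90   # label PIGD when ratio <= this


DEFAULT_SUBTYPE_CONFIG = SubtypeConfig()


@dataclass(frozen=True)
class SubtypeResult:
    tremor_score: float
    pigd_score: float
    ratio: Optional[float]  # undefined (None) when pigd_score == 0
    label: str              # "TD", "PIGD" or "IT"


def compute_subtype(updrs: MDSUPDRS,
                    config: SubtypeConfig = DEFAULT_SUBTYPE_CONFIG) -> SubtypeResult:
    """Classify the motor subtype from a scored MDS-UPDRS.

    Every configured item must be recorded (and in 0-4); otherwise
    :class:`MissingItemError` names the missing items.
    """
    missing = [c for c in config.tremor_items + config.pigd_items
               if updrs.item(c) is None]
    if missing:
        raise MissingItemError(missing)
    for code in config.tremor_items + config.pigd_items:
        v = updrs.item(code)
        if not 0 <= v <= 4:
            raise ValueError(f"MDS-UPDRS item {code} out of range 0-4: {v}")

    tremor = sum(updrs.item(c) for c in config.tremor_items) / len(config.tremor_items)
    pigd = sum(updrs.item(c) for c in config.pigd_items) / len(config.pigd_items)

    if pigd == 0:
        ratio = None
        label = "TD" if tremor > 0 else "IT"
    else:
        ratio = tremor / pigd
        if ratio >= config.td_threshold:
            label = "TD"
        elif ratio <= config.pigd_threshold:
            label = "PIGD"
        else:
            label = "IT"
    return SubtypeResult(tremor_score=tremor, pigd_score=pigd, ratio=ratio, label=label)
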
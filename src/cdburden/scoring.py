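"""Disease-activity scoring and health-utility scoring.

Two instruments are covered: the patient-completed Harvey-Bradshaw index
(item sum; a score above 4 defines active disease) and the EQ-5D-3L scored
against a pluggable three-level value set.  The packaged default value set
is the Polish TTO tariff; any 3L tariff expressed as additive decrements
(with an optional any-problem constant and any-level-3 term) can be loaded
from a CSV with the same schema.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Tuple

from .records import EQ5DState, PHBIResponse

logger = logging.getLogger(__name__)

__all__ = [
    "ValueSet3L",
    "PopulationNorms",
    "phbi_score",
    "classify_activity",
    "penetrating_course",
    "eq5d_utility",
    "matched_norm_utility",
    "load_value_set",
    "load_norms",
    "REMISSION",
    "ACTIVE",
]

REMISSION = "remission"
ACTIVE = "active"

#: Item score for an abdominal mass answered "present".  The clinician index
#: grades the mass 0-3 on palpation; a yes/no questionnaire answer is scored
#: with the lowest positive grade.
MASS_PRESENT_SCORE = 1


@dataclass
class ValueSet3L:
    """Additive three-level tariff: utility = 1 - sum of applicable decrements."""

    name: str = "unnamed"
    full_health_value: float = 1.0
    decrements: Mapping[Tuple[str, int], float] = field(default_factory=dict)
    constant_any_problem: float = 0.0
    any_level_3: float = 0.0

    def __post_init__(self) -> None:
        for (dim, level), dec in self.decrements.items():
            if level == 1 and dec != 0.0:
                raise ValueError(f"level-1 decrement must be 0 ({dim})")


@dataclass
class PopulationNorms:
    """Mean population utility by half-open age band [low, high) and sex."""

    bands: Tuple[Tuple[float, float, str, float], ...] = ()

    def lookup(self, age: float, sex: str) -> Optional[float]:
        for low, high, band_sex, value in self.bands:
            if band_sex == sex and low <= age < high:
                return value
        return None


def phbi_score(resp: PHBIResponse, include_mass: bool = True) -> Optional[int]:
    """Sum of item scores, or ``None`` when a mandatory item is missing.

    Mandatory items are wellbeing, pain and liquid stools.  Complications
    contribute one point each, but only those present in the previous week;
    the abdominal-mass answer contributes only when ``include_mass`` is set
    and the answer is definite ("unknown" scores zero).
    """
    if resp.general_wellbeing is None or resp.abdominal_pain is None or resp.liquid_stools_per_day is None:
        logger.debug("mandatory activity item missing; score set missing")
        return None
    score = int(resp.general_wellbeing) + int(resp.abdominal_pain) + int(resp.liquid_stools_per_day)
    if include_mass:
        if resp.abdominal_mass == "present":
            score += MASS_PRESENT_SCORE
        elif resp.abdominal_mass == "unknown":
            logger.debug("abdominal mass unknown; contributes 0")
    score += len(resp.complications_last_week)
    return score


def classify_activity(score: Optional[int]) -> Optional[str]:
    """Active disease iff the activity score exceeds 4 points."""
    if score is None:
        return None
    return ACTIVE if score > 4 else REMISSION


def penetrating_course(resp: PHBIResponse) -> bool:
    """Fistulising disease: a fistula reported last week or earlier."""
    return "fistula" in resp.complications_last_week or "fistula" in resp.complications_earlier


def eq5d_utility(state: EQ5DState, vs: ValueSet3L) -> Optional[float]:
    """Utility index of a 3L state under an additive value set.

    Returns ``None`` when any dimension level is missing.
    """
    if not state.complete():
        return None
    levels = state.levels()
    utility = vs.full_health_value
    if any(lv > 1 for lv in levels):
        utility -= vs.constant_any_problem
    if any(lv == 3 for lv in levels):
        utility -= vs.any_level_3
    for dim, lv in zip(EQ5DState.DIMENSIONS, levels):
        if lv > 1:
            utility -= vs.decrements.get((dim, lv), 0.0)
    return utility


def value_set_floor(vs: ValueSet3L) -> float:
    """Minimum utility over all 243 states (used to rescale utilities to [0, 1])."""
    from itertools import product

    worst = min(
        eq5d_utility(EQ5DState(*levels), vs) for levels in product((1, 2, 3), repeat=5)
    )
    return float(worst)


def matched_norm_utility(age: Optional[float], sex: Optional[str], norms: PopulationNorms) -> Optional[float]:
    """General-population utility for the respondent's age band and sex."""
    if age is None or sex is None:
        return None
    value = norms.lookup(age, sex)
    if value is None:
        logger.warning("no population norm for age %.1f / sex %s", age, sex)
    return value


def _read_packaged(name: str):
    return resources.files("cdburden.data").joinpath(name).read_text().splitlines()


def load_value_set(path: Optional[str] = None) -> ValueSet3L:
    """Load a value set from CSV (packaged Polish tariff when *path* is None)."""
    if path is None:
        lines = _read_packaged("value_set_pl.csv")
        name = "polish_tto"
    else:
        with open(path, newline="") as fh:
            lines = fh.read().splitlines()
        name = str(path)
    decrements: dict = {}
    constant = 0.0
    any3 = 0.0
    for row in csv.DictReader(lines):
        term = row["term"]
        if term == "constant_any_problem":
            constant = float(row["decrement"])
        elif term == "any_level_3":
            any3 = float(row["decrement"])
        else:
            decrements[(row["dimension"], int(row["level"]))] = float(row["decrement"])
    return ValueSet3L(name=name, decrements=decrements, constant_any_problem=constant, any_level_3=any3)


def load_norms(path: Optional[str] = None) -> PopulationNorms:
    """Load population norms from CSV (packaged Polish table when *path* is None)."""
    lines = _read_packaged("norms_pl.csv") if path is None else open(path).read().splitlines()
    bands = tuple(
        (float(r["age_low"]), float(r["age_high"]), r["sex"], float(r["utility"]))
        for r in csv.DictReader(lines)
    )
    return PopulationNorms(bands=bands)
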
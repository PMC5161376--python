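"""Domain types for respondent-level questionnaire data.

Every field of every record is independently "missable": ``None`` encodes a
missing answer throughout the package.  Monetary amounts are stored in EUR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "COMPLICATIONS",
    "TREATMENT_FLAGS",
    "CAREGIVER_TYPES",
    "PHBIResponse",
    "EQ5DState",
    "WorkRecord",
    "CareRecord",
    "ExpenseAnswer",
    "ResourceUseRecord",
    "TransferRecord",
    "PatientRecord",
    "UnitCostTable",
]

#: Complications asked about alongside the disease-activity items.
COMPLICATIONS = frozenset(
    {
        "arthralgia",
        "uveitis",
        "erythema_nodosum",
        "aphthous_ulcers",
        "pyoderma_gangrenosum",
        "anal_fissure",
        "fistula",
        "abscess",
    }
)

#: Drug-class flags collected by the questionnaire.
TREATMENT_FLAGS = frozenset(
    {
        "aminosalicylate",
        "immunosuppressant",
        "glucocorticoid",
        "biologic_adalimumab",
        "biologic_infliximab",
    }
)

#: Caregiver categories used to split replaced unpaid work from informal care.
CAREGIVER_TYPES = ("family_unpaid", "nonrelative_unpaid", "professional_or_paid")


@dataclass
class PHBIResponse:
    """Item-level answers to the patient-version disease-activity index."""

    general_wellbeing: Optional[int] = None  # 0..4
    abdominal_pain: Optional[int] = None  # 0..3
    liquid_stools_per_day: Optional[int] = None  # >= 0
    abdominal_mass: Optional[str] = None  # present | absent | unknown
    complications_last_week: frozenset = field(default_factory=frozenset)
    complications_earlier: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.complications_last_week = frozenset(self.complications_last_week)
        self.complications_earlier = frozenset(self.complications_earlier)


@dataclass
class EQ5DState:
    """Five dimension levels, each 1 (no problems) .. 3 (severe problems)."""

    mobility: Optional[int] = None
    self_care: Optional[int] = None
    usual_activities: Optional[int] = None
    pain: Optional[int] = None
    anxiety: Optional[int] = None

    DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain", "anxiety")

    def levels(self) -> tuple:
        return tuple(getattr(self, d) for d in self.DIMENSIONS)

    def complete(self) -> bool:
        return all(lv in (1, 2, 3) for lv in self.levels())


@dataclass
class WorkRecord:
    """Work status and paid-work loss answers.

    ``L_d``/``L_h`` are the respondent's maximum working time (days/month and
    hours/day); ``A_d`` is full days missed in the last month and ``A_h``
    single hours missed in the last five working days.
    """

    occupational_activity: Optional[bool] = None
    student: Optional[bool] = None
    retired: Optional[bool] = None
    on_pension: Optional[bool] = None
    pension_disability_level: Optional[float] = None  # fraction 0..1
    social_pension: Optional[bool] = None
    months_since_labour_market_departure: Optional[float] = None
    L_d: Optional[float] = None  # working days / month
    L_h: Optional[float] = None  # working hours / day
    A_d: Optional[float] = None  # full days missed / month
    A_h: Optional[float] = None  # single hours missed / 5 working days
    presenteeism_score: Optional[int] = None  # 0..10


@dataclass
class CareRecord:
    usual_activity_impairment_score: Optional[int] = None  # 0..10
    assistance_hours_per_week: Optional[Mapping[str, float]] = None

    def total_hours(self) -> Optional[float]:
        if self.assistance_hours_per_week is None:
            return None
        return float(sum(self.assistance_hours_per_week.values()))


@dataclass
class ExpenseAnswer:
    """Out-of-pocket expense answer: a predefined range or an open amount.

    Open amounts (used when spending exceeded the top predefined range) are
    stored with ``range_low == range_high == open value``.
    """

    range_low: Optional[float] = None
    range_high: Optional[float] = None

    @property
    def kind(self) -> Optional[str]:
        if self.range_low is None or self.range_high is None:
            return None
        return "open_amount" if self.range_low == self.range_high else "predefined_range"


@dataclass
class ResourceUseRecord:
    consultations_total: Optional[int] = None
    consultations_private: Optional[int] = None
    private_consultation_avg_cost: Optional[float] = None
    hospitalisation_count: Optional[int] = None
    hospital_days_total: Optional[float] = None
    one_day_hospitalisations: Optional[int] = None
    surgical_hospitalisation: Optional[bool] = None
    expense_range_meds: ExpenseAnswer = field(default_factory=ExpenseAnswer)
    expense_range_diet_transport: ExpenseAnswer = field(default_factory=ExpenseAnswer)
    expense_range_other: ExpenseAnswer = field(default_factory=ExpenseAnswer)


@dataclass
class TransferRecord:
    public_support_monthly: Optional[float] = None
    private_support_monthly: Optional[float] = None
    support_source_flags: frozenset = field(default_factory=frozenset)


@dataclass
class PatientRecord:
    """One respondent's full questionnaire response."""

    id: str = ""
    age: Optional[float] = None
    sex: Optional[str] = None  # male | female
    residence: Optional[str] = None
    age_at_diagnosis: Optional[float] = None
    comorbidities: Optional[bool] = None
    treatment_flags: frozenset = field(default_factory=frozenset)
    surgery_count: Optional[int] = None
    months_since_last_surgery: Optional[float] = None
    clinician_assessed_severity: Optional[str] = None  # remission_or_mild | moderate_or_severe | unknown
    phbi: PHBIResponse = field(default_factory=PHBIResponse)
    eq5d: EQ5DState = field(default_factory=EQ5DState)
    work: WorkRecord = field(default_factory=WorkRecord)
    care: CareRecord = field(default_factory=CareRecord)
    resource_use: ResourceUseRecord = field(default_factory=ResourceUseRecord)
    transfers: TransferRecord = field(default_factory=TransferRecord)

    def copy(self) -> "PatientRecord":
        return replace(
            self,
            phbi=replace(self.phbi),
            eq5d=replace(self.eq5d),
            work=replace(self.work),
            care=replace(
                self.care,
                assistance_hours_per_week=(
                    dict(self.care.assistance_hours_per_week)
                    if self.care.assistance_hours_per_week is not None
                    else None
                ),
            ),
            resource_use=replace(
                self.resource_use,
                expense_range_meds=replace(self.resource_use.expense_range_meds),
                expense_range_diet_transport=replace(self.resource_use.expense_range_diet_transport),
                expense_range_other=replace(self.resource_use.expense_range_other),
            ),
            transfers=replace(self.transfers),
        )


@dataclass
class UnitCostTable:
    """All monetary constants used by the cost engine (EUR).

    ``direct_costs`` prices consultations and hospitalisations; ``drugs``
    holds per-dose prices plus the dosing metadata needed to turn a treatment
    flag into a monthly consumption.
    """

    paid_work_hour: float = 8.34
    care_hour: float = 5.27
    monthly_working_hours: float = 168.0
    weeks_per_month: float = 4.345
    days_per_month: float = 30.44
    direct_costs: Mapping[str, float] = field(default_factory=dict)
    drugs: Mapping[str, Mapping] = field(default_factory=dict)
    flag_to_drug: Mapping[str, str] = field(default_factory=dict)
    default_body_weight_kg: float = 64.71
    biologic_diagnostics_monthly: float = 54.90
    pln_per_eur: float = 4.2624
    gdp_per_capita_annual: float = 10_900.0
    labour_elasticity: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 < self.labour_elasticity <= 1.0:
            raise ValueError("labour_elasticity must be in (0, 1]")
        for name in ("paid_work_hour", "care_hour", "pln_per_eur", "gdp_per_capita_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
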
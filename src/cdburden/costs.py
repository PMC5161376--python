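"""Monetary computation: productivity losses, care valuation, direct costs.

All amounts are EUR per month unless stated otherwise.  Paid-work losses are
valued with the human capital approach at a single hourly unit cost derived
from GDP per worker-hour scaled by the Cobb-Douglas labour elasticity;
unpaid work and informal care are valued at the average hourly wage
(opportunity cost); permanent work disability is costed with the prevalence
method (ongoing monthly lost output, no friction adjustment unless a
friction period is explicitly applied).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

import yaml

from .records import (
    CAREGIVER_TYPES,
    CareRecord,
    ExpenseAnswer,
    PatientRecord,
    ResourceUseRecord,
    UnitCostTable,
    WorkRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CostBreakdown",
    "load_unit_costs",
    "derive_paid_work_unit_cost",
    "absenteeism_fraction",
    "presenteeism_fraction",
    "overall_reduction",
    "paid_work_costs",
    "early_departure_cost",
    "apply_friction_period",
    "care_costs",
    "total_indirect",
    "direct_costs",
    "drug_monthly_cost",
    "out_of_pocket_valuation",
    "gdp_share",
    "convert_currency",
    "cost_breakdown",
]


@dataclass
class CostBreakdown:
    """Per-patient monthly cost components (EUR)."""

    absenteeism: Optional[float] = None
    presenteeism: Optional[float] = None
    early_departure: Optional[float] = None
    unpaid_work_loss: Optional[float] = None
    unpaid_work_uncompensated: Optional[float] = None
    informal_care: Optional[float] = None
    direct: Dict[str, Optional[float]] = field(default_factory=dict)
    out_of_pocket: Dict[str, Optional[Tuple[float, float, float]]] = field(default_factory=dict)
    transfers: Dict[str, Optional[float]] = field(default_factory=dict)
    hours_missed_absenteeism: Optional[float] = None
    hours_missed_presenteeism: Optional[float] = None


def load_unit_costs(path: Optional[str] = None) -> UnitCostTable:
    """Build a :class:`UnitCostTable` from YAML (packaged defaults if no path)."""
    if path is None:
        text = resources.files("cdburden.data").joinpath("unit_costs.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    raw.pop("macro", None)
    return UnitCostTable(**raw)


def derive_paid_work_unit_cost(
    gdp: float, workers: float, max_hours: float, elasticity: float
) -> float:
    """Hourly unit cost of paid-work productivity loss.

    GDP per worker-hour multiplied by the output elasticity of labour.
    """
    if gdp <= 0 or workers <= 0 or max_hours <= 0 or elasticity <= 0:
        raise ValueError("all unit-cost inputs must be positive")
    return gdp / (workers * max_hours) * elasticity


def absenteeism_fraction(
    A_d: Optional[float],
    A_h: Optional[float],
    L_d: Optional[float],
    L_h: Optional[float],
) -> Optional[float]:
    """Fraction of monthly working time lost to full days and single hours.

    R_A = [A_d * L_h + (A_h / 5) * (L_d - A_d)] / (L_d * L_h); single hours
    missed over the last five working days are extrapolated to the days
    actually worked.  Clamped to [0, 1] with a log note if clamping fires.
    """
    if A_d is None or A_h is None or L_d is None or L_h is None:
        return None
    if L_d <= 0 or L_h <= 0:
        return None
    r = (A_d * L_h + (A_h / 5.0) * (L_d - A_d)) / (L_d * L_h)
    if r < 0.0 or r > 1.0:
        logger.info("absenteeism fraction %.4f clamped to [0, 1]", r)
        r = min(1.0, max(0.0, r))
    return r


def presenteeism_fraction(score: Optional[int]) -> Optional[float]:
    """0-10 presenteeism score mapped to a fractional reduction (x 0.1)."""
    if score is None:
        return None
    if not 0 <= score <= 10:
        logger.info("presenteeism score %s out of range; set missing", score)
        return None
    return 0.1 * score


def overall_reduction(R_A: Optional[float], R_P: Optional[float]) -> Optional[float]:
    """Combined reduction: R_O = R_A + (1 - R_A) * R_P."""
    if R_A is None or R_P is None:
        return None
    return R_A + (1.0 - R_A) * R_P


def paid_work_costs(
    work: WorkRecord, unit_cost: float
) -> Tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """(absenteeism EUR, presenteeism EUR, hours absent, hours presenteeism).

    Monthly hours lost are L_d*L_h*R_A for absenteeism and
    L_d*L_h*(1-R_A)*R_P for presenteeism; each is valued at *unit_cost*.
    Respondents without occupational activity contribute zeros (they appear
    in cohort denominators with no paid work to lose).
    """
    if work.occupational_activity is None:
        return None, None, None, None
    if not work.occupational_activity:
        logger.debug("no occupational activity: paid-work costs not applicable (zero)")
        return 0.0, 0.0, 0.0, 0.0
    R_A = absenteeism_fraction(work.A_d, work.A_h, work.L_d, work.L_h)
    R_P = presenteeism_fraction(work.presenteeism_score)
    if R_A is None or R_P is None or work.L_d is None or work.L_h is None:
        return None, None, None, None
    monthly_hours = work.L_d * work.L_h
    hours_a = monthly_hours * R_A
    hours_p = monthly_hours * (1.0 - R_A) * R_P
    return hours_a * unit_cost, hours_p * unit_cost, hours_a, hours_p


def early_departure_cost(
    work: WorkRecord, unit_cost: float, monthly_hours: float = 168.0
) -> Optional[float]:
    """Monthly cost of registered early departure from the labour market.

    Prevalence method: disability level x standard monthly working hours x
    unit cost.  Social-pension recipients are assumed fully unable to work.
    Respondents not on a pension contribute zero.
    """
    if work.on_pension is None:
        return None
    if not work.on_pension:
        return 0.0
    if work.social_pension:
        level = 1.0
    elif work.pension_disability_level is not None:
        level = work.pension_disability_level
    else:
        logger.info("pensioner without disability level or social-pension flag; cost missing")
        return None
    return level * monthly_hours * unit_cost


def apply_friction_period(
    cost: Optional[float],
    months_since_departure: Optional[float],
    friction_days: Optional[float],
) -> Optional[float]:
    """Zero a departure cost once the friction period has elapsed.

    ``friction_days=None`` disables the adjustment (identity).  A missing
    departure time retains the cost, conservatively, with a warning.
    """
    if friction_days is None or cost is None:
        return cost
    if months_since_departure is None:
        if cost > 0:
            logger.warning("departure time missing with friction enabled; cost retained")
        return cost
    return cost if months_since_departure * 30.44 <= friction_days else 0.0


def care_costs(
    care: CareRecord, wage: float, weeks_per_month: float
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """(unpaid work loss, informal care, uncompensated unpaid work), EUR/month.

    Replaced unpaid work is all assistance time regardless of caregiver;
    informal care covers only unpaid caregivers (family and non-relatives);
    the uncompensated remainder is the professionally/paid-delivered part.
    All hours are weekly recall values scaled by *weeks_per_month* and valued
    at the opportunity-cost *wage*.
    """
    hours = care.assistance_hours_per_week
    if hours is None:
        return None, None, None
    total = sum(float(hours.get(k, 0.0)) for k in CAREGIVER_TYPES)
    informal = float(hours.get("family_unpaid", 0.0)) + float(hours.get("nonrelative_unpaid", 0.0))
    professional = float(hours.get("professional_or_paid", 0.0))
    factor = wage * weeks_per_month
    return total * factor, informal * factor, professional * factor


def total_indirect(cb: CostBreakdown, include_early_departure: bool = True) -> Optional[float]:
    """Sum of indirect components; missing any required part yields missing."""
    parts = [cb.absenteeism, cb.presenteeism, cb.unpaid_work_uncompensated, cb.informal_care]
    if include_early_departure:
        parts.append(cb.early_departure)
    if any(p is None for p in parts):
        return None
    return float(sum(parts))


def drug_monthly_cost(
    drug: str, unit_costs: UnitCostTable, body_weight: Optional[float] = None
) -> float:
    """Monthly cost of one drug at standard consumption.

    Oral drugs: one defined daily dose per day of the month (weight-based
    daily dose where the entry specifies mg/kg).  Biologics: annual
    consumption at recommended dosing divided by 12.
    """
    try:
        entry = unit_costs.drugs[drug]
    except KeyError:
        raise KeyError(f"drug {drug!r} absent from the unit-cost table") from None
    weight = body_weight if body_weight is not None else unit_costs.default_body_weight_kg
    price = float(entry["unit_cost"])
    if entry.get("kind") == "biologic":
        if "annual_mg" in entry:
            annual_mg = float(entry["annual_mg"])
        else:
            annual_mg = float(entry["annual_mg_per_kg"]) * weight
        return annual_mg / float(entry["unit_mg"]) * price / 12.0
    # oral: units per day; weight-based entries consume mg/kg/day of unit_mg doses
    if "mg_per_kg_per_day" in entry:
        units_per_day = float(entry["mg_per_kg_per_day"]) * weight / float(entry["unit_mg"])
    else:
        units_per_day = 1.0
    return units_per_day * unit_costs.days_per_month * price


def direct_costs(
    ru: ResourceUseRecord,
    treatment_flags,
    unit_costs: UnitCostTable,
    body_weight: Optional[float] = None,
) -> Dict[str, Optional[float]]:
    """Direct-cost component map (EUR/month).

    Components: publicly funded consultations, private consultations,
    hospitalisations (public payer) and current drug treatment (public
    payer, including monthly diagnostics for biologic users).
    """
    dc = unit_costs.direct_costs
    out: Dict[str, Optional[float]] = {}

    if ru.consultations_total is None or ru.consultations_private is None:
        out["consultations_public"] = None
        out["consultations_private"] = None
    else:
        public = max(0, ru.consultations_total - ru.consultations_private)
        out["consultations_public"] = public * dc["consultation_specialist"]
        if ru.consultations_private == 0:
            out["consultations_private"] = 0.0
        elif ru.private_consultation_avg_cost is None:
            out["consultations_private"] = None
        else:
            out["consultations_private"] = ru.consultations_private * ru.private_consultation_avg_cost

    if ru.hospitalisation_count is None:
        out["hospitalisations"] = None
    else:
        one_day = ru.one_day_hospitalisations or 0
        overnight = max(0, ru.hospitalisation_count - one_day)
        cost = one_day * dc["one_day_hospitalisation"]
        if overnight > 0 and ru.surgical_hospitalisation:
            cost += dc["surgical_hospitalisation"] + (overnight - 1) * dc["medical_hospitalisation"]
        else:
            cost += overnight * dc["medical_hospitalisation"]
        out["hospitalisations"] = cost

    treatment = 0.0
    any_biologic = False
    for flag in sorted(treatment_flags):
        drug = unit_costs.flag_to_drug.get(flag)
        if drug is None:
            raise KeyError(f"treatment flag {flag!r} has no drug mapping in the unit-cost table")
        treatment += drug_monthly_cost(drug, unit_costs, body_weight)
        if unit_costs.drugs[drug].get("kind") == "biologic":
            any_biologic = True
    if any_biologic:
        treatment += unit_costs.biologic_diagnostics_monthly
    out["treatment"] = treatment
    return out


def out_of_pocket_valuation(ans: ExpenseAnswer) -> Optional[Tuple[float, float, float]]:
    """(mean, min, max) EUR/month for a range or open expense answer."""
    if ans.range_low is None or ans.range_high is None:
        return None
    if ans.range_low > ans.range_high:
        logger.info("inverted expense range (%s, %s); set missing", ans.range_low, ans.range_high)
        return None
    return ((ans.range_low + ans.range_high) / 2.0, ans.range_low, ans.range_high)


def gdp_share(cost: float, gdp_per_capita_annual: float) -> float:
    """Monthly cost as a percentage of average monthly GDP per capita."""
    if gdp_per_capita_annual <= 0:
        raise ValueError("GDP per capita must be positive")
    return cost / (gdp_per_capita_annual / 12.0) * 100.0


def convert_currency(amount_pln: float, rate: float) -> float:
    """PLN to EUR at the configured exchange rate."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_pln / rate


def cost_breakdown(
    record: PatientRecord,
    unit_costs: UnitCostTable,
    friction_days: Optional[float] = None,
    body_weight: Optional[float] = None,
) -> CostBreakdown:
    """Full monthly cost breakdown for one respondent."""
    cb = CostBreakdown()
    cb.absenteeism, cb.presenteeism, cb.hours_missed_absenteeism, cb.hours_missed_presenteeism = (
        paid_work_costs(record.work, unit_costs.paid_work_hour)
    )
    ed = early_departure_cost(record.work, unit_costs.paid_work_hour, unit_costs.monthly_working_hours)
    cb.early_departure = apply_friction_period(
        ed, record.work.months_since_labour_market_departure, friction_days
    )
    cb.unpaid_work_loss, cb.informal_care, cb.unpaid_work_uncompensated = care_costs(
        record.care, unit_costs.care_hour, unit_costs.weeks_per_month
    )
    cb.direct = direct_costs(record.resource_use, record.treatment_flags, unit_costs, body_weight)
    cb.out_of_pocket = {
        "meds": out_of_pocket_valuation(record.resource_use.expense_range_meds),
        "diet_transport": out_of_pocket_valuation(record.resource_use.expense_range_diet_transport),
        "other": out_of_pocket_valuation(record.resource_use.expense_range_other),
    }
    cb.transfers = {
        "public": record.transfers.public_support_monthly,
        "private": record.transfers.private_support_monthly,
    }
    return cb
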
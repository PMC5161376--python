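"""Cohort readers/writers and the answer-consistency validation rules.

The canonical file layout is a flat table (CSV or XLSX) with one row per
respondent and the column dictionary below.  Foreign layouts are mapped onto
the canonical headers through a YAML column mapping ``{foreign: canonical}``.
Unparseable cells become missing values; they never fail the row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .records import (
    CAREGIVER_TYPES,
    COMPLICATIONS,
    CareRecord,
    EQ5DState,
    ExpenseAnswer,
    PatientRecord,
    PHBIResponse,
    ResourceUseRecord,
    TransferRecord,
    TREATMENT_FLAGS,
    WorkRecord,
)

logger = logging.getLogger(__name__)

__all__ = ["CohortDialect", "COLUMN_DICTIONARY", "read_cohort", "write_cohort", "validate_record"]

_SET_SEP = ";"

#: Canonical column names and the field they populate.
COLUMN_DICTIONARY: Tuple[str, ...] = (
    "id", "age", "sex", "residence", "age_at_diagnosis", "comorbidities",
    "treatment_flags", "surgery_count", "months_since_last_surgery",
    "clinician_assessed_severity",
    "phbi_wellbeing", "phbi_pain", "phbi_liquid_stools", "phbi_mass",
    "phbi_complications_last_week", "phbi_complications_earlier",
    "eq5d_mobility", "eq5d_self_care", "eq5d_usual_activities", "eq5d_pain", "eq5d_anxiety",
    "work_occupational_activity", "work_student", "work_retired", "work_on_pension",
    "work_social_pension", "work_pension_disability_level", "work_months_since_departure",
    "work_days_per_month", "work_hours_per_day", "work_days_missed",
    "work_hours_missed_5d", "work_presenteeism_score",
    "care_impairment_score", "care_hours_family", "care_hours_nonrelative",
    "care_hours_professional",
    "ru_consultations_total", "ru_consultations_private", "ru_private_consultation_cost",
    "ru_hospitalisation_count", "ru_hospital_days", "ru_one_day_hospitalisations",
    "ru_surgical_hospitalisation",
    "exp_meds_low", "exp_meds_high",
    "exp_diet_transport_low", "exp_diet_transport_high",
    "exp_other_low", "exp_other_high",
    "transfer_public_monthly", "transfer_private_monthly", "transfer_sources",
)


@dataclass
class CohortDialect:
    """How to interpret a cohort file.

    ``column_map`` renames foreign headers to canonical ones before parsing;
    ``currency`` declares the unit of monetary columns (PLN inputs are
    converted to EUR on read at ``pln_per_eur``).
    """

    column_map: Dict[str, str] = field(default_factory=dict)
    currency: str = "EUR"
    pln_per_eur: float = 4.2624


_MONETARY_COLUMNS = frozenset(
    {
        "ru_private_consultation_cost",
        "exp_meds_low", "exp_meds_high",
        "exp_diet_transport_low", "exp_diet_transport_high",
        "exp_other_low", "exp_other_high",
        "transfer_public_monthly", "transfer_private_monthly",
    }
)

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def _parse_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def _parse_int(v) -> Optional[int]:
    f = _parse_float(v)
    if f is None or f != int(f):
        return None if f is None else int(round(f))
    return int(f)


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return None


def _parse_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s or None


def _parse_set(v, allowed: frozenset) -> frozenset:
    s = _parse_str(v)
    if s is None:
        return frozenset()
    items = {tok.strip() for tok in s.split(_SET_SEP) if tok.strip()}
    unknown = items - allowed
    if unknown:
        logger.warning("ignoring unknown set items %s", sorted(unknown))
    return frozenset(items & allowed)


def _row_to_record(row: Dict) -> PatientRecord:
    g = row.get
    rec = PatientRecord(
        id=_parse_str(g("id")) or "",
        age=_parse_float(g("age")),
        sex=_parse_str(g("sex")),
        residence=_parse_str(g("residence")),
        age_at_diagnosis=_parse_float(g("age_at_diagnosis")),
        comorbidities=_parse_bool(g("comorbidities")),
        treatment_flags=_parse_set(g("treatment_flags"), TREATMENT_FLAGS),
        surgery_count=_parse_int(g("surgery_count")),
        months_since_last_surgery=_parse_float(g("months_since_last_surgery")),
        clinician_assessed_severity=_parse_str(g("clinician_assessed_severity")),
        phbi=PHBIResponse(
            general_wellbeing=_parse_int(g("phbi_wellbeing")),
            abdominal_pain=_parse_int(g("phbi_pain")),
            liquid_stools_per_day=_parse_int(g("phbi_liquid_stools")),
            abdominal_mass=_parse_str(g("phbi_mass")),
            complications_last_week=_parse_set(g("phbi_complications_last_week"), COMPLICATIONS),
            complications_earlier=_parse_set(g("phbi_complications_earlier"), COMPLICATIONS),
        ),
        eq5d=EQ5DState(
            mobility=_parse_int(g("eq5d_mobility")),
            self_care=_parse_int(g("eq5d_self_care")),
            usual_activities=_parse_int(g("eq5d_usual_activities")),
            pain=_parse_int(g("eq5d_pain")),
            anxiety=_parse_int(g("eq5d_anxiety")),
        ),
        work=WorkRecord(
            occupational_activity=_parse_bool(g("work_occupational_activity")),
            student=_parse_bool(g("work_student")),
            retired=_parse_bool(g("work_retired")),
            on_pension=_parse_bool(g("work_on_pension")),
            social_pension=_parse_bool(g("work_social_pension")),
            pension_disability_level=_parse_float(g("work_pension_disability_level")),
            months_since_labour_market_departure=_parse_float(g("work_months_since_departure")),
            L_d=_parse_float(g("work_days_per_month")),
            L_h=_parse_float(g("work_hours_per_day")),
            A_d=_parse_float(g("work_days_missed")),
            A_h=_parse_float(g("work_hours_missed_5d")),
            presenteeism_score=_parse_int(g("work_presenteeism_score")),
        ),
        care=CareRecord(
            usual_activity_impairment_score=_parse_int(g("care_impairment_score")),
            assistance_hours_per_week=_parse_care_hours(row),
        ),
        resource_use=ResourceUseRecord(
            consultations_total=_parse_int(g("ru_consultations_total")),
            consultations_private=_parse_int(g("ru_consultations_private")),
            private_consultation_avg_cost=_parse_float(g("ru_private_consultation_cost")),
            hospitalisation_count=_parse_int(g("ru_hospitalisation_count")),
            hospital_days_total=_parse_float(g("ru_hospital_days")),
            one_day_hospitalisations=_parse_int(g("ru_one_day_hospitalisations")),
            surgical_hospitalisation=_parse_bool(g("ru_surgical_hospitalisation")),
            expense_range_meds=ExpenseAnswer(_parse_float(g("exp_meds_low")), _parse_float(g("exp_meds_high"))),
            expense_range_diet_transport=ExpenseAnswer(
                _parse_float(g("exp_diet_transport_low")), _parse_float(g("exp_diet_transport_high"))
            ),
            expense_range_other=ExpenseAnswer(_parse_float(g("exp_other_low")), _parse_float(g("exp_other_high"))),
        ),
        transfers=TransferRecord(
            public_support_monthly=_parse_float(g("transfer_public_monthly")),
            private_support_monthly=_parse_float(g("transfer_private_monthly")),
            support_source_flags=_parse_set(
                g("transfer_sources"),
                frozenset(
                    {"social_pension", "disability_pension", "rehabilitation", "nursing", "other_public", "relatives_or_ngo"}
                ),
            ),
        ),
    )
    return rec


def _parse_care_hours(row: Dict) -> Optional[Dict[str, float]]:
    cols = ("care_hours_family", "care_hours_nonrelative", "care_hours_professional")
    vals = [_parse_float(row.get(c)) for c in cols]
    if all(v is None for v in vals):
        return None
    return {k: (v if v is not None else 0.0) for k, v in zip(CAREGIVER_TYPES, vals)}


def _convert_pln(df: pd.DataFrame, rate: float) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        if col in _MONETARY_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce") / rate
    return df


def read_cohort(path: str, dialect: Optional[CohortDialect] = None) -> List[PatientRecord]:
    """Read a cohort file into validated :class:`PatientRecord` objects.

    Unknown columns are ignored with a warning; an empty file yields an empty
    cohort with a warning.  Each record is passed through
    :func:`validate_record` so cross-field inconsistencies become missing.
    """
    dialect = dialect or CohortDialect()
    if str(path).endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if dialect.column_map:
        df = df.rename(columns=dialect.column_map)
    unknown = [c for c in df.columns if c not in COLUMN_DICTIONARY]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
        df = df.drop(columns=unknown)
    if dialect.currency.upper() == "PLN":
        df = _convert_pln(df, dialect.pln_per_eur)
    if df.empty:
        logger.warning("cohort file %s contains no rows", path)
        return []
    records = []
    for _, row in df.iterrows():
        rec = _row_to_record(row.to_dict())
        rec, _notes = validate_record(rec)
        records.append(rec)
    return records


def _record_to_row(rec: PatientRecord) -> Dict:
    hours = rec.care.assistance_hours_per_week
    return {
        "id": rec.id,
        "age": rec.age,
        "sex": rec.sex,
        "residence": rec.residence,
        "age_at_diagnosis": rec.age_at_diagnosis,
        "comorbidities": rec.comorbidities,
        "treatment_flags": _SET_SEP.join(sorted(rec.treatment_flags)) or None,
        "surgery_count": rec.surgery_count,
        "months_since_last_surgery": rec.months_since_last_surgery,
        "clinician_assessed_severity": rec.clinician_assessed_severity,
        "phbi_wellbeing": rec.phbi.general_wellbeing,
        "phbi_pain": rec.phbi.abdominal_pain,
        "phbi_liquid_stools": rec.phbi.liquid_stools_per_day,
        "phbi_mass": rec.phbi.abdominal_mass,
        "phbi_complications_last_week": _SET_SEP.join(sorted(rec.phbi.complications_last_week)) or None,
        "phbi_complications_earlier": _SET_SEP.join(sorted(rec.phbi.complications_earlier)) or None,
        "eq5d_mobility": rec.eq5d.mobility,
        "eq5d_self_care": rec.eq5d.self_care,
        "eq5d_usual_activities": rec.eq5d.usual_activities,
        "eq5d_pain": rec.eq5d.pain,
        "eq5d_anxiety": rec.eq5d.anxiety,
        "work_occupational_activity": rec.work.occupational_activity,
        "work_student": rec.work.student,
        "work_retired": rec.work.retired,
        "work_on_pension": rec.work.on_pension,
        "work_social_pension": rec.work.social_pension,
        "work_pension_disability_level": rec.work.pension_disability_level,
        "work_months_since_departure": rec.work.months_since_labour_market_departure,
        "work_days_per_month": rec.work.L_d,
        "work_hours_per_day": rec.work.L_h,
        "work_days_missed": rec.work.A_d,
        "work_hours_missed_5d": rec.work.A_h,
        "work_presenteeism_score": rec.work.presenteeism_score,
        "care_impairment_score": rec.care.usual_activity_impairment_score,
        "care_hours_family": None if hours is None else hours.get("family_unpaid", 0.0),
        "care_hours_nonrelative": None if hours is None else hours.get("nonrelative_unpaid", 0.0),
        "care_hours_professional": None if hours is None else hours.get("professional_or_paid", 0.0),
        "ru_consultations_total": rec.resource_use.consultations_total,
        "ru_consultations_private": rec.resource_use.consultations_private,
        "ru_private_consultation_cost": rec.resource_use.private_consultation_avg_cost,
        "ru_hospitalisation_count": rec.resource_use.hospitalisation_count,
        "ru_hospital_days": rec.resource_use.hospital_days_total,
        "ru_one_day_hospitalisations": rec.resource_use.one_day_hospitalisations,
        "ru_surgical_hospitalisation": rec.resource_use.surgical_hospitalisation,
        "exp_meds_low": rec.resource_use.expense_range_meds.range_low,
        "exp_meds_high": rec.resource_use.expense_range_meds.range_high,
        "exp_diet_transport_low": rec.resource_use.expense_range_diet_transport.range_low,
        "exp_diet_transport_high": rec.resource_use.expense_range_diet_transport.range_high,
        "exp_other_low": rec.resource_use.expense_range_other.range_low,
        "exp_other_high": rec.resource_use.expense_range_other.range_high,
        "transfer_public_monthly": rec.transfers.public_support_monthly,
        "transfer_private_monthly": rec.transfers.private_support_monthly,
        "transfer_sources": _SET_SEP.join(sorted(rec.transfers.support_source_flags)) or None,
    }


def write_cohort(records: Sequence[PatientRecord], path: str) -> None:
    """Write records to CSV using the canonical column dictionary."""
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=COLUMN_DICTIONARY)
    df.to_csv(path, index=False)


def validate_record(record: PatientRecord) -> Tuple[PatientRecord, List[str]]:
    """Replace internally inconsistent answers with missing values.

    Never raises and never drops the record: only the offending fields are
    blanked, keeping per-outcome denominators intact.  Idempotent.
    """
    rec = record.copy()
    notes: List[str] = []

    if rec.age is not None and rec.age_at_diagnosis is not None and rec.age_at_diagnosis > rec.age:
        notes.append(f"age_at_diagnosis {rec.age_at_diagnosis} > age {rec.age}: set missing")
        rec.age_at_diagnosis = None

    w = rec.work
    if w.A_d is not None and w.L_d is not None and w.A_d > w.L_d:
        notes.append(f"days missed {w.A_d} > working days {w.L_d}: set missing")
        w.A_d = None
    if w.A_d is not None and w.A_d < 0:
        notes.append("negative days missed: set missing")
        w.A_d = None
    if w.A_h is not None and w.A_h < 0:
        notes.append("negative hours missed: set missing")
        w.A_h = None
    if w.A_h is not None and w.L_h is not None and w.A_h > 5 * w.L_h:
        notes.append(f"single hours missed {w.A_h} exceed 5-day working time: set missing")
        w.A_h = None
    if w.presenteeism_score is not None and not 0 <= w.presenteeism_score <= 10:
        notes.append(f"presenteeism score {w.presenteeism_score} outside 0..10: set missing")
        w.presenteeism_score = None
    if w.pension_disability_level is not None and w.on_pension is not True:
        notes.append("disability level without pension: set missing")
        w.pension_disability_level = None
    if w.pension_disability_level is not None and not 0 <= w.pension_disability_level <= 1:
        notes.append("disability level outside [0, 1]: set missing")
        w.pension_disability_level = None

    c = rec.care
    if c.usual_activity_impairment_score is not None and not 0 <= c.usual_activity_impairment_score <= 10:
        notes.append("impairment score outside 0..10: set missing")
        c.usual_activity_impairment_score = None
    if c.assistance_hours_per_week is not None and any(v < 0 for v in c.assistance_hours_per_week.values()):
        notes.append("negative assistance hours: set missing")
        c.assistance_hours_per_week = None

    ru = rec.resource_use
    if (
        ru.consultations_total is not None
        and ru.consultations_private is not None
        and ru.consultations_private > ru.consultations_total
    ):
        notes.append(
            f"private consultations {ru.consultations_private} > total {ru.consultations_total}: both set missing"
        )
        ru.consultations_total = None
        ru.consultations_private = None
    for label, ans in (
        ("meds", ru.expense_range_meds),
        ("diet_transport", ru.expense_range_diet_transport),
        ("other", ru.expense_range_other),
    ):
        if ans.range_low is not None and ans.range_high is not None and ans.range_low > ans.range_high:
            notes.append(f"inverted expense range ({label}): set missing")
            ans.range_low = None
            ans.range_high = None

    for note in notes:
        logger.info("validation [%s]: %s", rec.id, note)
    return rec, notes
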
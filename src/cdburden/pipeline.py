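"""Pipeline orchestration: read/generate -> validate -> score -> cost -> compare.

Outputs are plain CSV tables mirroring the study's reporting structure
(cohort characteristics, costs by severity, overall monthly costs, the
inferential statistics) plus a JSON manifest sufficient to reproduce the
bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .costs import cost_breakdown, gdp_share, load_unit_costs, total_indirect
from .io import CohortDialect, read_cohort, validate_record, write_cohort
from .records import PatientRecord, UnitCostTable
from .scoring import (
    ACTIVE,
    REMISSION,
    classify_activity,
    eq5d_utility,
    load_norms,
    load_value_set,
    matched_norm_utility,
    penetrating_course,
    phbi_score,
    value_set_floor,
)
from .stats import (
    agreement,
    describe,
    fractional_logit_means,
    signed_rank_test,
    spearman_rho,
    two_part_cost_model,
)
from .synth import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "score_cohort", "cost_cohort", "summarize_figures", "analyze_cohort"]

#: Covariate sets supported by the adjusted models.
COVARIATE_SETS = {
    "full": ("sex", "age", "age_at_diagnosis", "comorbidities", "surgery", "pension"),
    "reduced": ("age", "age_at_diagnosis", "comorbidities", "surgery"),
    "none": (),
}


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    unit_cost_path: Optional[str] = None
    include_mass: bool = True
    friction_days: Optional[float] = None
    covariate_set: str = "full"
    out_dir: str = "cdburden_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one input source (file or generator) must be given")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")


def score_cohort(
    records: Sequence[PatientRecord],
    value_set=None,
    norms=None,
    include_mass: bool = True,
) -> pd.DataFrame:
    """Per-respondent scores: disease activity, utility and norm utility."""
    vs = value_set or load_value_set()
    nm = norms or load_norms()
    rows = []
    for rec in records:
        score = phbi_score(rec.phbi, include_mass=include_mass)
        rows.append(
            {
                "id": rec.id,
                "age": rec.age,
                "sex": rec.sex,
                "age_at_diagnosis": rec.age_at_diagnosis,
                "comorbidities": rec.comorbidities,
                "surgery": None if rec.surgery_count is None else rec.surgery_count > 0,
                "pension": rec.work.on_pension,
                "occupational_activity": rec.work.occupational_activity,
                "student": rec.work.student,
                "retired": rec.work.retired,
                "phbi_score": score,
                "activity": classify_activity(score),
                "penetrating": penetrating_course(rec.phbi),
                "clinician_assessed_severity": rec.clinician_assessed_severity,
                "utility": eq5d_utility(rec.eq5d, vs),
                "norm_utility": matched_norm_utility(rec.age, rec.sex, nm),
                "presenteeism_score": rec.work.presenteeism_score,
                "impairment_score": rec.care.usual_activity_impairment_score,
                "assistance_hours": rec.care.total_hours(),
            }
        )
    df = pd.DataFrame(rows)
    numeric = [
        "age",
        "age_at_diagnosis",
        "phbi_score",
        "utility",
        "norm_utility",
        "presenteeism_score",
        "impairment_score",
        "assistance_hours",
    ]
    df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")
    return df


def cost_cohort(
    records: Sequence[PatientRecord],
    unit_costs: Optional[UnitCostTable] = None,
    friction_days: Optional[float] = None,
) -> pd.DataFrame:
    """Per-respondent monthly cost breakdown as a flat table (EUR)."""
    uc = unit_costs or load_unit_costs()
    rows = []
    for rec in records:
        cb = cost_breakdown(rec, uc, friction_days=friction_days)
        oop = {f"oop_{k}": (v[0] if v else None) for k, v in cb.out_of_pocket.items()}
        oop_lo = {f"oop_{k}_min": (v[1] if v else None) for k, v in cb.out_of_pocket.items()}
        oop_hi = {f"oop_{k}_max": (v[2] if v else None) for k, v in cb.out_of_pocket.items()}
        rows.append(
            {
                "id": rec.id,
                "absenteeism": cb.absenteeism,
                "presenteeism": cb.presenteeism,
                "early_departure": cb.early_departure,
                "unpaid_work_loss": cb.unpaid_work_loss,
                "unpaid_work_uncompensated": cb.unpaid_work_uncompensated,
                "informal_care": cb.informal_care,
                "hours_missed_absenteeism": cb.hours_missed_absenteeism,
                "hours_missed_presenteeism": cb.hours_missed_presenteeism,
                "total_indirect": total_indirect(cb, include_early_departure=True),
                "total_indirect_short_term": total_indirect(cb, include_early_departure=False),
                "direct_consultations_public": cb.direct.get("consultations_public"),
                "direct_consultations_private": cb.direct.get("consultations_private"),
                "direct_hospitalisations": cb.direct.get("hospitalisations"),
                "direct_treatment": cb.direct.get("treatment"),
                **oop,
                **oop_lo,
                **oop_hi,
                "transfer_public": cb.transfers.get("public"),
                "transfer_private": cb.transfers.get("private"),
            }
        )
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c != "id"]
    df[value_cols] = df[value_cols].apply(pd.to_numeric, errors="coerce")
    return df


def _mean_sd_n(series: pd.Series) -> Dict[str, float]:
    s = describe(series.tolist())
    if s is None:
        return {"n": 0, "mean": np.nan, "sd": np.nan}
    return {"n": s.n, "mean": s.mean, "sd": s.sd}


def summarize_figures(
    df: pd.DataFrame, outcomes: Sequence[str], group_col: str = "activity"
) -> pd.DataFrame:
    """Box-whisker numeric content per subgroup and outcome."""
    rows = []
    subgroups = ["all"] + sorted(g for g in df[group_col].dropna().unique())
    for outcome in outcomes:
        for sub in subgroups:
            sel = df if sub == "all" else df[df[group_col] == sub]
            s = describe(sel[outcome].tolist())
            if s is None:
                logger.info("summarize_figures: empty subgroup %s for %s; omitted", sub, outcome)
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "subgroup": sub,
                    "n": s.n,
                    "min": s.min,
                    "p5": s.p5,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "p95": s.p95,
                    "max": s.max,
                    "mean": s.mean,
                }
            )
    return pd.DataFrame(rows)


def _covariate_matrix(scored: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    cov = pd.DataFrame(index=scored.index)
    for name in names:
        if name == "sex":
            cov[name] = scored["sex"].map({"male": 1.0, "female": 0.0})
        elif name in ("comorbidities", "surgery", "pension"):
            cov[name] = scored[name].map({True: 1.0, False: 0.0})
        else:
            cov[name] = pd.to_numeric(scored[name], errors="coerce")
    return cov


def _adjusted_contrast(outcome: pd.Series, scored: pd.DataFrame, covariate_set: str, model: str):
    names = COVARIATE_SETS[covariate_set]
    frame = pd.DataFrame({"y": outcome, "g": (scored["activity"] == REMISSION).where(scored["activity"].notna())})
    cov = _covariate_matrix(scored, names)
    frame = pd.concat([frame, cov], axis=1).dropna()
    if frame.empty or frame["g"].nunique() < 2:
        return None
    covariates = frame[list(names)].to_numpy() if names else None
    fn = fractional_logit_means if model == "fractional_logit" else two_part_cost_model
    try:
        return fn(frame["y"].to_numpy(dtype=float), frame["g"].to_numpy(dtype=float), covariates)
    except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
        # small cohorts can yield singular or separated designs; report the
        # contrast as unavailable instead of aborting the bundle
        logger.warning("adjusted %s model failed (%s); contrast omitted", model, exc)
        return None


def analyze_cohort(
    scored: pd.DataFrame,
    costs: pd.DataFrame,
    unit_costs: UnitCostTable,
    covariate_set: str = "full",
) -> pd.DataFrame:
    """Tidy statistics table: correlations, agreement, adjusted contrasts."""
    rows: List[Dict] = []

    def add(name, estimate, **kw):
        rows.append({"statistic": name, "estimate": estimate, **kw})

    rho, p = spearman_rho(scored["utility"], scored["phbi_score"])
    add("spearman_utility_vs_activity_score", rho, p_value=p)
    rho, p = spearman_rho(scored["presenteeism_score"], scored["phbi_score"])
    add("spearman_presenteeism_vs_activity_score", rho, p_value=p)
    rho, p = spearman_rho(scored["impairment_score"], scored["phbi_score"])
    add("spearman_impairment_vs_activity_score", rho, p_value=p)

    clin = scored["clinician_assessed_severity"].map(
        {"remission_or_mild": REMISSION, "moderate_or_severe": ACTIVE}
    )
    pct, kappa = agreement(scored["activity"].tolist(), clin.tolist())
    add("percent_agreement_activity_vs_clinician", pct)
    add("kappa_activity_vs_clinician", kappa)

    paired = scored[["utility", "norm_utility"]].dropna()
    if len(paired) >= 5 and not (paired["utility"] == paired["norm_utility"]).all():
        stat, p = signed_rank_test(paired["utility"].tolist(), paired["norm_utility"].tolist())
        add("signed_rank_utility_vs_norm", stat, p_value=p)

    # utilities can be negative under a 3L tariff: rescale to [0, 1] for the
    # fractional logit, then map the contrast back to the utility scale
    floor = min(0.0, value_set_floor(load_value_set()))
    span = 1.0 - floor
    rescaled = (scored["utility"] - floor) / span
    contrast = _adjusted_contrast(rescaled, scored, covariate_set, "fractional_logit")
    if contrast is not None:
        add(
            "adjusted_utility_difference_remission_minus_active",
            contrast.difference * span,
            ci_low=contrast.ci_low * span,
            ci_high=contrast.ci_high * span,
            p_value=contrast.p_value,
        )
    for component in ("absenteeism", "presenteeism", "unpaid_work_loss", "informal_care", "total_indirect_short_term"):
        contrast = _adjusted_contrast(costs[component], scored, covariate_set, "two_part")
        if contrast is not None:
            add(
                f"adjusted_{component}_difference_remission_minus_active",
                contrast.difference,
                ci_low=contrast.ci_low,
                ci_high=contrast.ci_high,
                p_value=contrast.p_value,
            )

    ti = costs["total_indirect"].dropna()
    if len(ti):
        add("mean_total_indirect", float(ti.mean()), n=int(len(ti)))
        add("total_indirect_gdp_share_pct", gdp_share(float(ti.mean()), unit_costs.gdp_per_capita_annual))
    return pd.DataFrame(rows)


def _characteristics_table(scored: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sub in ["all", REMISSION, ACTIVE]:
        sel = scored if sub == "all" else scored[scored["activity"] == sub]
        if sel.empty:
            continue
        def pct(col: str) -> float:
            vals = sel[col].map({True: 1.0, False: 0.0}) if sel[col].dtype == object else sel[col]
            return 100.0 * pd.to_numeric(vals, errors="coerce").mean()

        rows.append(
            {
                "subgroup": sub,
                "n": len(sel),
                "age_mean": sel["age"].mean(),
                "male_pct": 100.0 * (sel["sex"] == "male").mean(),
                "age_at_diagnosis_mean": sel["age_at_diagnosis"].mean(),
                "comorbidities_pct": pct("comorbidities"),
                "phbi_mean": sel["phbi_score"].mean(),
                "occupational_activity_pct": pct("occupational_activity"),
                "pension_pct": pct("pension"),
                "student_pct": pct("student"),
                "penetrating_pct": pct("penetrating"),
            }
        )
    return pd.DataFrame(rows)


def _costs_table(costs: pd.DataFrame, scored: pd.DataFrame) -> pd.DataFrame:
    components = [
        "absenteeism",
        "early_departure",
        "presenteeism",
        "unpaid_work_loss",
        "unpaid_work_uncompensated",
        "informal_care",
        "total_indirect",
        "direct_consultations_public",
        "direct_consultations_private",
        "direct_hospitalisations",
        "direct_treatment",
        "oop_meds",
        "oop_diet_transport",
        "oop_other",
        "transfer_public",
        "transfer_private",
    ]
    merged = costs.merge(scored[["id", "activity"]], on="id")
    rows = []
    for comp in components:
        row = {"component": comp, **_mean_sd_n(costs[comp])}
        for sub in (REMISSION, ACTIVE):
            sel = merged[merged["activity"] == sub]
            stats = _mean_sd_n(sel[comp])
            row[f"{sub}_mean"] = stats["mean"]
            row[f"{sub}_sd"] = stats["sd"]
            row[f"{sub}_n"] = stats["n"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute the full pipeline and write the report bundle.

    Returns a mapping of artefact name to written path.  Identical
    (config, seed) pairs produce byte-identical numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    uc = load_unit_costs(config.unit_cost_path)

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        records = generate_cohort(gen)
        validated = []
        for rec in records:
            v, notes = validate_record(rec)
            for note in notes:
                logger.info("validation [%s]: %s", rec.id, note)
            validated.append(v)
        records = validated
    else:
        records = read_cohort(config.input_path)

    scored = score_cohort(records, include_mass=config.include_mass)
    costs = cost_cohort(records, uc, friction_days=config.friction_days)

    artefacts: Dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        artefacts[name] = path

    cohort_path = out / "cohort.csv"
    write_cohort(records, str(cohort_path))
    artefacts["cohort"] = cohort_path

    save("scores", scored)
    save("costs", costs)
    save("table_characteristics", _characteristics_table(scored))
    save("table_costs", _costs_table(costs, scored))
    merged = scored.merge(costs, on="id")
    save(
        "figures_summary",
        summarize_figures(
            merged,
            ["utility", "presenteeism_score", "impairment_score", "assistance_hours", "total_indirect"],
        ),
    )
    save("statistics", analyze_cohort(scored, costs, uc, covariate_set=config.covariate_set))

    manifest = {
        "config": {
            "input_path": config.input_path,
            "generator": dataclasses.asdict(config.generator) if config.generator else None,
            "unit_cost_path": config.unit_cost_path,
            "include_mass": config.include_mass,
            "friction_days": config.friction_days,
            "covariate_set": config.covariate_set,
            "seed": config.seed,
        },
        "versions": {"cdburden": __version__, "python": platform.python_version()},
        "n_records": len(records),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    artefacts["manifest"] = manifest_path
    return artefacts
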
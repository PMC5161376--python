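"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces questionnaire records with a two-stratum
(remission/active) severity structure, zero-inflated right-skewed loss
outcomes, utility decreasing in disease activity and impairment increasing
in it.  Default parameters are calibrated to published cohort marginals
(stratum sizes, employment, pension, treatment rates, activity-score
means); the distributional forms themselves are implementation choices.

One master seed drives a fixed per-component spawn schedule
(strata, demographics, activity items, health states, work, care, resource
use, expenses, transfers) so each component can be regenerated
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .records import (
    CareRecord,
    EQ5DState,
    ExpenseAnswer,
    PatientRecord,
    PHBIResponse,
    ResourceUseRecord,
    TransferRecord,
    WorkRecord,
)
from .scoring import ACTIVE, REMISSION

__all__ = ["GeneratorConfig", "generate_cohort", "generate_two_group_costs", "generate_two_group_fractions"]

_COMPONENTS = (
    "strata",
    "demographics",
    "phbi",
    "eq5d",
    "work",
    "care",
    "resource",
    "expense",
    "transfer",
)

#: Predefined out-of-pocket expense ranges (EUR/month); the last entry is the
#: open-answer regime above the top range.
EXPENSE_RANGES: Tuple[Tuple[float, float], ...] = ((0.0, 23.5), (23.5, 46.9), (46.9, 93.8), (93.8, 140.8))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GeneratorConfig:
    n: int = 200
    seed: int = 0
    remission_fraction: float = 0.47
    employment_prob: Dict[str, float] = field(default_factory=lambda: {REMISSION: 0.645, ACTIVE: 0.552})
    pension_prob: Dict[str, float] = field(default_factory=lambda: {REMISSION: 0.043, ACTIVE: 0.152})
    student_prob: Dict[str, float] = field(default_factory=lambda: {REMISSION: 0.226, ACTIVE: 0.20})
    retired_prob: float = 0.02
    # activity score: remission = Binomial(4, p); active = 5 + NegBin(shape, mean)
    phbi_params: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            REMISSION: {"n": 4, "p": 0.47},
            ACTIVE: {"mean_excess": 4.2, "shape": 3.0},
        }
    )
    # zero-inflation logits and positive-part scales for days/hours missed
    absence_params: Dict[str, float] = field(
        default_factory=lambda: {
            "days_zero_intercept": -2.2,
            "days_zero_slope": 0.18,
            "days_pos_rate": 0.5,
            "hours_zero_intercept": -1.8,
            "hours_zero_slope": 0.15,
            "hours_pos_mean": 3.0,
        }
    )
    # mean presenteeism score grows linearly with the activity score
    presenteeism_link: Dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.0, "slope": 0.55, "sd": 1.8}
    )
    care_params: Dict[str, float] = field(
        default_factory=lambda: {
            "any_intercept": -3.0,
            "any_slope": 0.28,
            "family_shape": 1.52,
            "family_scale": 5.37,
            "nonrelative_prob": 0.2,
            "nonrelative_shape": 4.0,
            "nonrelative_scale": 0.7,
            "professional_prob": 0.05,
            "professional_mean": 4.0,
            "impairment_slope": 0.6,
            "impairment_sd": 1.6,
        }
    )
    # per-dimension (threshold-for-some, threshold-for-severe, slope)
    eq5d_link: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "mobility": (-4.0, -9.0, 0.35),
            "self_care": (-5.0, -10.0, 0.25),
            "usual_activities": (-2.8, -7.5, 0.35),
            "pain": (-1.2, -5.5, 0.35),
            "anxiety": (-1.0, -5.0, 0.30),
        }
    )
    # categorical probabilities over the predefined ranges + open answers
    expense_params: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {
            "meds": (0.35, 0.30, 0.25, 0.07, 0.03),
            "diet_transport": (0.55, 0.25, 0.13, 0.05, 0.02),
            "other": (0.93, 0.05, 0.015, 0.005, 0.0),
        }
    )

    def validate(self) -> None:
        probs = [self.remission_fraction, self.retired_prob]
        probs += list(self.employment_prob.values())
        probs += list(self.pension_prob.values())
        probs += list(self.student_prob.values())
        for cat in self.expense_params.values():
            probs += list(cat)
            if not np.isclose(sum(cat), 1.0):
                raise ValueError("expense category probabilities must sum to 1")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")


def _component_rngs(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_COMPONENTS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_COMPONENTS, children)}


def _draw_phbi_scores(strata: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    scores = np.empty(len(strata), dtype=int)
    rem = strata == REMISSION
    p = cfg.phbi_params[REMISSION]
    scores[rem] = rng.binomial(int(p["n"]), p["p"], size=int(rem.sum()))
    a = cfg.phbi_params[ACTIVE]
    shape, mean = a["shape"], a["mean_excess"]
    pr = shape / (shape + mean)
    scores[~rem] = 5 + rng.negative_binomial(shape, pr, size=int((~rem).sum()))
    return scores


_COMPLICATION_POOL = (
    "arthralgia",
    "aphthous_ulcers",
    "anal_fissure",
    "abscess",
    "erythema_nodosum",
    "uveitis",
    "fistula",
    "pyoderma_gangrenosum",
)


def _decompose_score(score: int, rng: np.random.Generator) -> PHBIResponse:
    """Split a target activity score into item answers that sum back to it."""
    remaining = score
    wellbeing = int(rng.integers(0, min(4, remaining) + 1))
    remaining -= wellbeing
    pain = int(rng.integers(0, min(3, remaining) + 1))
    remaining -= pain
    n_compl = int(rng.integers(0, min(3, remaining) + 1))
    remaining -= n_compl
    complications = frozenset(rng.choice(_COMPLICATION_POOL, size=n_compl, replace=False)) if n_compl else frozenset()
    return PHBIResponse(
        general_wellbeing=wellbeing,
        abdominal_pain=pain,
        liquid_stools_per_day=remaining,  # unbounded item absorbs the rest
        abdominal_mass="absent",
        complications_last_week=complications,
        complications_earlier=frozenset(),
    )


def _draw_eq5d(score: int, cfg: GeneratorConfig, rng: np.random.Generator) -> EQ5DState:
    levels = {}
    for dim, (a2, a3, slope) in cfg.eq5d_link.items():
        u = rng.random()
        p_some = _sigmoid(a2 + slope * score)
        p_severe = _sigmoid(a3 + slope * score)
        levels[dim] = 3 if u < p_severe else (2 if u < p_some else 1)
    return EQ5DState(**levels)


def generate_cohort(config: Optional[GeneratorConfig] = None) -> List[PatientRecord]:
    """Generate a synthetic cohort; deterministic given (seed, config)."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rngs = _component_rngs(cfg.seed)
    n = cfg.n

    strata = np.where(rngs["strata"].random(n) < cfg.remission_fraction, REMISSION, ACTIVE)
    scores = _draw_phbi_scores(strata, cfg, rngs["phbi"])

    records: List[PatientRecord] = []
    for i in range(n):
        stratum = str(strata[i])
        score = int(scores[i])
        rec = PatientRecord(id=f"SYN{i:05d}")
        _fill_demographics(rec, stratum, rngs["demographics"])
        rec.phbi = _decompose_score(score, rngs["phbi"])
        if rngs["phbi"].random() < (0.204 if stratum == REMISSION else 0.333):
            rec.phbi.complications_earlier = rec.phbi.complications_earlier | {"fistula"}
        rec.eq5d = _draw_eq5d(score, cfg, rngs["eq5d"])
        rec.work = _draw_work(stratum, score, cfg, rngs["work"])
        rec.care = _draw_care(score, cfg, rngs["care"])
        rec.resource_use = _draw_resource_use(score, cfg, rngs["resource"], rngs["expense"])
        rec.transfers = _draw_transfers(rec.work, rngs["transfer"])
        records.append(rec)
    return records


def _fill_demographics(rec: PatientRecord, stratum: str, rng: np.random.Generator) -> None:
    rec.age = float(np.clip(np.round(rng.normal(31.8, 10.4), 1), 18.0, 80.0))
    rec.sex = "male" if rng.random() < 0.422 else "female"
    rec.residence = str(rng.choice(["city_large", "city_small", "rural"], p=[0.55, 0.3, 0.15]))
    rec.age_at_diagnosis = float(max(5.0, np.round(rec.age - rng.gamma(2.0, 3.7), 1)))
    rec.comorbidities = bool(rng.random() < (0.376 if stratum == REMISSION else 0.476))
    flags = set()
    if rng.random() < (0.806 if stratum == REMISSION else 0.857):
        flags.add("aminosalicylate")
    if rng.random() < (0.559 if stratum == REMISSION else 0.476):
        flags.add("immunosuppressant")
    if rng.random() < (0.140 if stratum == REMISSION else 0.352):
        flags.add("glucocorticoid")
    if rng.random() < (0.108 if stratum == REMISSION else 0.171):
        flags.add("biologic_adalimumab" if rng.random() < 0.5 else "biologic_infliximab")
    rec.treatment_flags = frozenset(flags)
    if rng.random() < (0.409 if stratum == REMISSION else 0.515):
        rec.surgery_count = int(rng.geometric(0.7))
        rec.months_since_last_surgery = float(np.round(rng.lognormal(np.log(30.0), 0.9), 1))
    else:
        rec.surgery_count = 0
        rec.months_since_last_surgery = None
    sev_probs = (0.903, 0.065, 0.032) if stratum == REMISSION else (0.543, 0.419, 0.038)
    rec.clinician_assessed_severity = str(
        rng.choice(["remission_or_mild", "moderate_or_severe", "unknown"], p=sev_probs)
    )


def _draw_work(stratum: str, score: int, cfg: GeneratorConfig, rng: np.random.Generator) -> WorkRecord:
    ap = cfg.absence_params
    pl = cfg.presenteeism_link
    work = WorkRecord()
    work.occupational_activity = bool(rng.random() < cfg.employment_prob[stratum])
    work.student = bool(rng.random() < cfg.student_prob[stratum])
    work.retired = bool(rng.random() < cfg.retired_prob)
    work.on_pension = bool(rng.random() < cfg.pension_prob[stratum])
    if work.on_pension:
        if rng.random() < 0.42:
            work.social_pension = True
        else:
            work.social_pension = False
            work.pension_disability_level = float(rng.choice([0.5, 0.75, 1.0], p=[0.25, 0.25, 0.5]))
        work.months_since_labour_market_departure = float(np.round(12.0 + rng.exponential(24.0), 1))
    else:
        work.social_pension = False
    if work.occupational_activity:
        work.L_d = float(rng.choice([18, 20, 21, 22], p=[0.05, 0.1, 0.75, 0.1]))
        work.L_h = float(rng.choice([6, 7, 8], p=[0.08, 0.07, 0.85]))
        if rng.random() < _sigmoid(ap["days_zero_intercept"] + ap["days_zero_slope"] * score):
            work.A_d = float(min(work.L_d, 1 + rng.poisson(ap["days_pos_rate"] * score)))
        else:
            work.A_d = 0.0
        if rng.random() < _sigmoid(ap["hours_zero_intercept"] + ap["hours_zero_slope"] * score):
            work.A_h = float(min(5 * work.L_h, np.round(rng.exponential(ap["hours_pos_mean"]), 1)))
        else:
            work.A_h = 0.0
        work.presenteeism_score = int(
            np.clip(np.round(rng.normal(pl["intercept"] + pl["slope"] * score, pl["sd"])), 0, 10)
        )
    return work


def _draw_care(score: int, cfg: GeneratorConfig, rng: np.random.Generator) -> CareRecord:
    cp = cfg.care_params
    care = CareRecord()
    care.usual_activity_impairment_score = int(
        np.clip(np.round(rng.normal(cp["impairment_slope"] * score, cp["impairment_sd"])), 0, 10)
    )
    hours = {"family_unpaid": 0.0, "nonrelative_unpaid": 0.0, "professional_or_paid": 0.0}
    if rng.random() < _sigmoid(cp["any_intercept"] + cp["any_slope"] * score):
        hours["family_unpaid"] = float(np.round(rng.gamma(cp["family_shape"], cp["family_scale"]), 1))
        if rng.random() < cp["nonrelative_prob"]:
            hours["nonrelative_unpaid"] = float(np.round(rng.gamma(cp["nonrelative_shape"], cp["nonrelative_scale"]), 1))
        if rng.random() < cp["professional_prob"]:
            hours["professional_or_paid"] = float(np.round(rng.exponential(cp["professional_mean"]), 1))
    care.assistance_hours_per_week = hours
    return care


def _draw_resource_use(
    score: int, cfg: GeneratorConfig, rng: np.random.Generator, rng_exp: np.random.Generator
) -> ResourceUseRecord:
    ru = ResourceUseRecord()
    if rng.random() < 0.70:
        ru.consultations_total = 1 + int(rng.poisson(0.9))
    else:
        ru.consultations_total = 0
    ru.consultations_private = int(rng.binomial(ru.consultations_total, 0.33))
    if ru.consultations_private > 0:
        ru.private_consultation_avg_cost = float(np.round(max(5.0, rng.normal(36.61, 15.94)), 2))
    if rng.random() < _sigmoid(-2.0 + 0.12 * score):
        ru.hospitalisation_count = 1 + int(rng.poisson(0.3))
        ru.one_day_hospitalisations = int(rng.binomial(ru.hospitalisation_count, 0.5))
        ru.surgical_hospitalisation = bool(rng.random() < 0.0625)
        overnight = ru.hospitalisation_count - ru.one_day_hospitalisations
        ru.hospital_days_total = float(overnight * (1 + rng.poisson(3.0)) + ru.one_day_hospitalisations)
    else:
        ru.hospitalisation_count = 0
        ru.one_day_hospitalisations = 0
        ru.surgical_hospitalisation = False
        ru.hospital_days_total = 0.0
    ru.expense_range_meds = _draw_expense("meds", cfg, rng_exp)
    ru.expense_range_diet_transport = _draw_expense("diet_transport", cfg, rng_exp)
    ru.expense_range_other = _draw_expense("other", cfg, rng_exp)
    return ru


def _draw_expense(category: str, cfg: GeneratorConfig, rng: np.random.Generator) -> ExpenseAnswer:
    probs = np.asarray(cfg.expense_params[category], dtype=float)
    idx = int(rng.choice(len(probs), p=probs))
    if idx < len(EXPENSE_RANGES):
        low, high = EXPENSE_RANGES[idx]
        return ExpenseAnswer(range_low=low, range_high=high)
    open_value = float(np.round(EXPENSE_RANGES[-1][1] + rng.exponential(60.0), 2))
    return ExpenseAnswer(range_low=open_value, range_high=open_value)


def _draw_transfers(work: WorkRecord, rng: np.random.Generator) -> TransferRecord:
    tr = TransferRecord()
    sources = set()
    public = 0.0
    if work.on_pension:
        public += float(np.round(rng.lognormal(np.log(150.0), 0.4), 2))
        sources.add("social_pension" if work.social_pension else "disability_pension")
    if rng.random() < 0.10:
        public += float(np.round(rng.lognormal(np.log(40.0), 0.5), 2))
        sources.add("nursing")
    tr.public_support_monthly = public
    if rng.random() < 0.19:
        tr.private_support_monthly = float(np.round(rng.gamma(1.2, 60.0), 2))
        sources.add("relatives_or_ngo")
    else:
        tr.private_support_monthly = 0.0
    tr.support_source_flags = frozenset(sources)
    return tr


def generate_two_group_costs(
    n_per_group: Union[int, Tuple[int, int]],
    group_effect: float,
    zero_prob: Tuple[float, float] = (0.5, 0.35),
    seed: int = 0,
    base_mean: float = 200.0,
    shape: float = 0.8,
    dist: str = "gamma",
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-group zero-inflated cost samples.

    Group 1's total mean exceeds group 0's by *group_effect* in expectation;
    positive parts are gamma (default) or log-normal.  Returns
    ``(costs, group_indicator)``.
    """
    if isinstance(n_per_group, int):
        n0 = n1 = n_per_group
    else:
        n0, n1 = n_per_group
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 observations per group")
    if not all(0.0 <= p <= 1.0 for p in zero_prob):
        raise ValueError("zero probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ys, gs = [], []
    for g, n, zp, mean in ((0, n0, zero_prob[0], base_mean), (1, n1, zero_prob[1], base_mean + group_effect)):
        nonzero = rng.random(n) >= zp
        y = np.zeros(n)
        if zp < 1.0 and mean > 0:
            pos_mean = mean / (1.0 - zp)
            k = nonzero.sum()
            if dist == "gamma":
                y[nonzero] = rng.gamma(shape, pos_mean / shape, size=k)
            elif dist == "lognormal":
                sigma = 1.0
                y[nonzero] = rng.lognormal(np.log(pos_mean) - sigma**2 / 2.0, sigma, size=k)
            else:
                raise ValueError(f"unknown positive-part distribution {dist!r}")
        ys.append(y)
        gs.append(np.full(n, g))
    return np.concatenate(ys), np.concatenate(gs)


def generate_two_group_fractions(
    n_per_group: Union[int, Tuple[int, int]],
    means: Tuple[float, float] = (0.78, 0.90),
    concentration: float = 8.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-group fractional outcomes in [0, 1] with a built-in mean shift."""
    if isinstance(n_per_group, int):
        n0 = n1 = n_per_group
    else:
        n0, n1 = n_per_group
    rng = np.random.default_rng(seed)
    ys, gs = [], []
    for g, n, m in ((0, n0, means[0]), (1, n1, means[1])):
        ys.append(rng.beta(m * concentration, (1.0 - m) * concentration, size=n))
        gs.append(np.full(n, g))
    return np.concatenate(ys), np.concatenate(gs)
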
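"""Inferential layer: descriptives, rank statistics, agreement, adjusted
subgroup contrasts (fractional logit, two-part cost models) and the
design-stage sample-size computation.

Adjusted contrasts are average adjusted predictions: every respondent is
counterfactually assigned to each group, predictions are averaged, and the
group difference is equipped with a delta-method confidence interval using
robust (sandwich) parameter covariances.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptiveSummary",
    "AdjustedContrast",
    "describe",
    "spearman_rho",
    "rank_sum_test",
    "signed_rank_test",
    "chi2_test",
    "group_tests",
    "agreement",
    "fractional_logit_means",
    "two_part_cost_model",
    "model_selection_diagnostics",
    "required_sample_size",
]


@dataclass
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    min: float
    max: float


@dataclass
class AdjustedContrast:
    adjusted_means: Dict[int, float]
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    covariate_list: Tuple[str, ...] = ()
    flags: List[str] = field(default_factory=list)


def _clean(values) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return arr[~np.isnan(arr)]


def describe(values) -> Optional[DescriptiveSummary]:
    """Moments and quantiles (linear interpolation between order statistics)."""
    arr = _clean(values)
    if arr.size == 0:
        logger.info("describe: empty series after missing exclusion")
        return None
    q = np.percentile(arr, [5, 25, 50, 75, 95])
    return DescriptiveSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(q[2]),
        q1=float(q[1]),
        q3=float(q[3]),
        p5=float(q[0]),
        p95=float(q[4]),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def _paired_clean(x, y) -> Tuple[np.ndarray, np.ndarray]:
    pairs = [
        (a, b)
        for a, b in zip(x, y)
        if a is not None and b is not None and not (isinstance(a, float) and math.isnan(a)) and not (isinstance(b, float) and math.isnan(b))
    ]
    if not pairs:
        return np.array([]), np.array([])
    ax, ay = map(np.asarray, zip(*pairs))
    return ax.astype(float), ay.astype(float)


def spearman_rho(x, y) -> Tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation with mid-ranks for ties."""
    ax, ay = _paired_clean(x, y)
    if ax.size < 3:
        return None, None
    if np.all(ax == ax[0]) or np.all(ay == ay[0]):
        logger.info("spearman: degenerate (constant) series")
        return None, None
    rho, p = sps.spearmanr(ax, ay)
    return float(rho), float(p)


def rank_sum_test(x, y) -> Tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, mid-ranks for ties."""
    res = sps.mannwhitneyu(_clean(x), _clean(y), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x, y) -> Tuple[float, float]:
    """Paired Wilcoxon signed-rank test; zero differences are dropped."""
    ax, ay = _paired_clean(x, y)
    res = sps.wilcoxon(ax, ay, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def chi2_test(labels, groups) -> Tuple[float, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    la = [(a, b) for a, b in zip(labels, groups) if a is not None and b is not None]
    a, b = zip(*la)
    cats_a, cats_b = sorted(set(a)), sorted(set(b))
    table = np.zeros((len(cats_a), len(cats_b)))
    for va, vb in la:
        table[cats_a.index(va), cats_b.index(vb)] += 1
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def group_tests(values, groups, kind: str = "ranksum"):
    """Dispatch to the subgroup comparison appropriate for the outcome type."""
    if kind == "ranksum":
        gs = sorted({g for g in groups if g is not None})
        if len(gs) != 2:
            raise ValueError("rank-sum comparison needs exactly two groups")
        x = [v for v, g in zip(values, groups) if g == gs[0] and v is not None]
        y = [v for v, g in zip(values, groups) if g == gs[1] and v is not None]
        if not x or not y:
            return None, None
        return rank_sum_test(x, y)
    if kind == "signedrank":
        return signed_rank_test(values, groups)
    if kind == "chi2":
        return chi2_test(values, groups)
    raise ValueError(f"unknown test kind {kind!r}")


def agreement(labels_a, labels_b) -> Tuple[Optional[float], Optional[float]]:
    """(percentage agreement, Cohen's kappa) over complete label pairs.

    Kappa uses chance agreement from the product of marginal distributions;
    it is undefined (None) when both raters use a single category.
    """
    def missing(v) -> bool:
        return v is None or (isinstance(v, float) and math.isnan(v))

    pairs = [(a, b) for a, b in zip(labels_a, labels_b) if not missing(a) and not missing(b)]
    if not pairs:
        return None, None
    n = len(pairs)
    p_o = sum(a == b for a, b in pairs) / n
    cats = sorted({c for pair in pairs for c in pair})
    pa = {c: sum(a == c for a, _ in pairs) / n for c in cats}
    pb = {c: sum(b == c for _, b in pairs) / n for c in cats}
    p_e = sum(pa[c] * pb[c] for c in cats)
    if p_e == 1.0:
        logger.info("agreement: single category observed; kappa undefined")
        return 100.0 * p_o, None
    kappa = (p_o - p_e) / (1.0 - p_e)
    return 100.0 * p_o, kappa


def _design(group: np.ndarray, covariates: Optional[np.ndarray]) -> Tuple[np.ndarray, Tuple[str, ...]]:
    cols = [np.ones_like(group, dtype=float), group.astype(float)]
    names = ["const", "group"]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == group.size and cov.shape[1] != group.size:
            cov = cov.T
        for j in range(cov.shape[0]):
            cols.append(cov[j])
            names.append(f"x{j}")
    return np.column_stack(cols), tuple(names)


def _counterfactual(X: np.ndarray, g: int) -> np.ndarray:
    Xg = X.copy()
    Xg[:, 1] = float(g)
    return Xg


def _contrast_from_grad(diff, grad, cov, means, names, flags) -> AdjustedContrast:
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = diff / se
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 1.0 if diff == 0 else 0.0
    zc = sps.norm.ppf(0.975)
    return AdjustedContrast(
        adjusted_means=means,
        difference=diff,
        ci_low=diff - zc * se,
        ci_high=diff + zc * se,
        p_value=p,
        covariate_list=names[2:],
        flags=flags,
    )


def fractional_logit_means(
    outcome, group, covariates=None
) -> AdjustedContrast:
    """Adjusted group means of a fractional outcome via quasi-binomial logit.

    The difference reported is mean(group 1) - mean(group 0), with a
    delta-method CI based on the robust (HC1) covariance.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractional outcome must lie in [0, 1]")
    X, names = _design(g, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(cov_type="HC1")
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("fractional logit did not converge to finite estimates")
    cov = np.asarray(res.cov_params())
    beta = res.params

    def aap(gval: int):
        Xg = _counterfactual(X, gval)
        eta = Xg @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = (p * (1.0 - p))[:, None] * Xg
        return float(p.mean()), grad.mean(axis=0)

    m0, g0 = aap(0)
    m1, g1 = aap(1)
    return _contrast_from_grad(m1 - m0, g1 - g0, cov, {0: m0, 1: m1}, names, [])


def two_part_cost_model(cost, group, covariates=None) -> AdjustedContrast:
    """Two-part model for non-negative costs with a mass at zero.

    Part 1 is a logistic model for any cost; part 2 a log-link gamma GLM on
    positive costs.  Adjusted means combine both parts; the group marginal
    effect carries a delta-method CI from robust part-wise covariances
    (the parts are asymptotically independent).
    """
    y = np.asarray(cost, dtype=float)
    g = np.asarray(group, dtype=float)
    if np.any(y < 0):
        raise ValueError("costs must be non-negative")
    flags: List[str] = []
    pos = y > 0
    groups_present = sorted(set(g))

    if not pos.any():
        flags.append("all costs zero; degenerate model")
        return AdjustedContrast({0: 0.0, 1: 0.0}, 0.0, 0.0, 0.0, 1.0, (), flags)

    pos_by_group = {gv: bool(pos[g == gv].any()) for gv in groups_present}
    if not all(pos_by_group.values()):
        # one group entirely at zero: its adjusted mean is structurally 0
        zero_gv = [gv for gv, has in pos_by_group.items() if not has][0]
        other = [gv for gv in groups_present if gv != zero_gv][0]
        flags.append(f"group {zero_gv:g} has no positive costs; part-2 fit skipped for it")
        mean_other = float(y[g == other].mean())
        diff = (mean_other if other == 1 else -mean_other)
        return AdjustedContrast({int(zero_gv): 0.0, int(other): mean_other}, diff, diff, diff, float("nan"), (), flags)

    X, names = _design(g, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        part1 = sm.GLM(pos.astype(float), X, family=sm.families.Binomial()).fit(cov_type="HC1")
        part2 = sm.GLM(y[pos], X[pos], family=sm.families.Gamma(link=sm.families.links.Log())).fit(
            cov_type="HC1"
        )
    beta, gamma = part1.params, part2.params
    cov1 = np.asarray(part1.cov_params())
    cov2 = np.asarray(part2.cov_params())

    def aap(gval: int):
        Xg = _counterfactual(X, gval)
        p = 1.0 / (1.0 + np.exp(-(Xg @ beta)))
        mu = np.exp(Xg @ gamma)
        mean = float((p * mu).mean())
        grad_b = ((p * (1.0 - p) * mu)[:, None] * Xg).mean(axis=0)
        grad_g = ((p * mu)[:, None] * Xg).mean(axis=0)
        return mean, np.concatenate([grad_b, grad_g])

    m0, g0 = aap(0)
    m1, g1 = aap(1)
    k = len(beta)
    cov = np.zeros((2 * k, 2 * k))
    cov[:k, :k] = cov1
    cov[k:, k:] = cov2
    return _contrast_from_grad(m1 - m0, g1 - g0, cov, {0: m0, 1: m1}, names, flags)


_FAMILY_BY_POWER = {0: "gaussian", 1: "poisson", 2: "gamma", 3: "inverse_gaussian"}


def model_selection_diagnostics(y, mu) -> Optional[Dict[str, object]]:
    """Modified Park test on the positive-cost part.

    Regresses squared raw-scale residuals on the log of fitted means with a
    log link; the slope estimates the variance power (0 gaussian, 1 poisson,
    2 gamma, 3 inverse gaussian).  Returns None when fewer than 10 positive
    observations with non-degenerate residuals are available.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    keep = (y > 0) & (mu > 0)
    y, mu = y[keep], mu[keep]
    resid2 = (y - mu) ** 2
    ok = resid2 > 0
    if ok.sum() < 10 or np.ptp(mu[ok]) == 0:
        logger.info("park test: insufficient usable positive observations")
        return None
    X = np.column_stack([np.ones(ok.sum()), np.log(mu[ok])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(resid2[ok], X, family=sm.families.Gamma(link=sm.families.links.Log())).fit(
            cov_type="HC0"
        )
    lam = float(fit.params[1])
    recommended = _FAMILY_BY_POWER[min(_FAMILY_BY_POWER, key=lambda k: abs(k - lam))]
    return {
        "park_coefficient": lam,
        "recommended_family": recommended,
        "loglike": float(fit.llf),
    }


def required_sample_size(
    delta: float,
    sd_active: float,
    variance_ratio: float = 0.5,
    power: float = 0.8,
    alpha: float = 0.05,
    missing_rate: float = 0.0,
    allocation: float = 1.0,
) -> int:
    """Per-group sample size to detect a mean difference of *delta*.

    Normal-approximation two-sample formula with unequal variances: the
    reference group variance is ``sd_active**2`` and the other group's is
    scaled by *variance_ratio*; the result is inflated for the expected
    missing-response rate and rounded up.
    """
    if delta <= 0 or sd_active <= 0:
        raise ValueError("delta and sd_active must be positive")
    if not (0.0 < power < 1.0) or not (0.0 < alpha < 1.0):
        raise ValueError("power and alpha must lie in (0, 1)")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    var_a = sd_active**2
    var_r = var_a * variance_ratio
    n = z**2 * (var_a + var_r / allocation) / delta**2
    n /= 1.0 - missing_rate
    return int(math.ceil(n))
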
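"""Group-comparison and diagnostic-accuracy statistics.

Implements the statistical toolkit of the study: Welch's two-sample t-test
with Satterthwaite degrees of freedom, paired t-tests between stimulus
conditions, Spearman rank correlation against clinical covariates,
empirical ROC curves with Mann–Whitney AUC and DeLong confidence
intervals, strict Bonferroni significance decisions, and the binormal
sensitivity/specificity ↔ Cohen's d analytics used to reason about the
diagnostic ceiling of a candidate biomarker.

Standard distributions and tests come from scipy/statsmodels; the DeLong
AUC covariance is implemented here (midrank placement method) since no
installed package exposes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "GroupStats",
    "RocResult",
    "CorrelationResult",
    "welch_t",
    "paired_t",
    "spearman",
    "roc_auc",
    "bonferroni",
    "binormal_d_for_sens_spec",
    "binormal_auc",
    "power_two_sample",
]


@dataclass(frozen=True)
class GroupStats:
    mean_a: float
    ci_a: tuple[float, float]
    n_a: int
    mean_b: float
    ci_b: tuple[float, float]
    n_b: int
    statistic: float
    df: float
    p_value: float
    mean_difference: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    positive_label: int = 1
    sensitivity_at_specificity: float | None = None
    requested_specificity: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    m = float(values.mean())
    if n < 2:
        return (m, m)
    se = float(values.std(ddof=1)) / np.sqrt(n)
    half = sps.t.ppf(0.5 + level / 2, n - 1) * se
    return (m - half, m + half)


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> GroupStats:
    """Welch's unequal-variance two-sample t-test, two-sided.

    When both groups have zero variance and equal means the statistic is
    0/0; by convention the test is reported as no evidence (t=0, p=1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            t_stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            t_stat, p, df = np.inf * np.sign(a.mean() - b.mean()), 0.0, float(
                a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupStats(
        mean_a=float(a.mean()), ci_a=_t_ci(a), n_a=a.size,
        mean_b=float(b.mean()), ci_b=_t_ci(b), n_b=b.size,
        statistic=t_stat, df=df, p_value=p,
        mean_difference=float(a.mean() - b.mean()))


def paired_t(condition_a: np.ndarray, condition_b: np.ndarray) -> GroupStats:
    """Paired t-test: one-sample t on the within-participant differences."""
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired conditions must have equal length")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0.0:
        t_stat = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
        p = 1.0 if d.mean() == 0.0 else 0.0
    else:
        res = sps.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupStats(
        mean_a=float(a.mean()), ci_a=_t_ci(a), n_a=a.size,
        mean_b=float(b.mean()), ci_b=_t_ci(b), n_b=b.size,
        statistic=t_stat, df=float(a.size - 1), p_value=p,
        mean_difference=float(d.mean()))


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation with midrank ties, two-sided p.

    Uses the exact permutation null for n < 10 and the t approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant input")
    n = x.size
    rho, p_asym = sps.spearmanr(x, y)
    if n < 10:
        # Exact permutation p-value.  With fixed rank vectors, |rho| is a
        # monotone function of |Σ rx·ry − c|, so only the dot product is
        # needed per permutation.
        from itertools import permutations

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        c = float(rx.sum()) * float(ry.sum()) / n
        obs = abs(float(rx @ ry) - c)
        count = 0
        total = 0
        for perm in permutations(ry):
            count += abs(float(rx @ np.asarray(perm)) - c) >= obs - 1e-9
            total += 1
        p = count / total
    else:
        p = float(p_asym)
    return CorrelationResult(rho=float(rho), p_value=p, n=n)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    rk_all = _midrank(allv)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    # placement values: P(neg < pos_i) and P(pos > neg_j), ties half
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            positive_label: int = 1, level: float = 0.95,
            at_specificity: float | None = None) -> RocResult:
    """Empirical ROC AUC with DeLong confidence interval.

    AUC is the Mann–Whitney probability that a positive-class score exceeds
    a negative-class one (ties count one half); it is reported in the raw
    orientation (higher score = more positive-like), so values below 0.5
    indicate the opposite direction of effect.  ``at_specificity`` requests
    the empirical sensitivity at the smallest achievable specificity >= the
    request.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc, var = _delong_variance(pos, neg)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)

    sens = None
    if at_specificity is not None:
        thresholds = np.unique(scores)
        best = None
        # classify "score >= thr" as positive; pick max sensitivity among
        # thresholds meeting the specificity request
        for thr in thresholds:
            spec = float(np.mean(neg < thr))
            if spec >= at_specificity:
                s = float(np.mean(pos >= thr))
                best = s if best is None else max(best, s)
        sens = 0.0 if best is None else best
    return RocResult(auc=auc, ci_lower=lo, ci_upper=hi,
                     positive_label=positive_label,
                     sensitivity_at_specificity=sens,
                     requested_specificity=at_specificity)


def bonferroni(p_values: np.ndarray | list[float], family_size: int = 4,
               alpha: float = 0.05) -> list[bool]:
    """Strict Bonferroni decisions: significant iff p < alpha/family_size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    threshold = alpha / family_size
    return [float(p) < threshold for p in np.atleast_1d(p_values)]


def binormal_d_for_sens_spec(sensitivity: float, specificity: float) -> float:
    """Group separation (Cohen's d) needed for a sensitivity/specificity pair.

    For two equal-variance normal score distributions and a single decision
    threshold, d = Φ⁻¹(sensitivity) + Φ⁻¹(specificity).
    """
    if not (0.0 < sensitivity < 1.0 and 0.0 < specificity < 1.0):
        raise ValueError("sensitivity and specificity must be inside (0, 1)")
    return float(sps.norm.ppf(sensitivity) + sps.norm.ppf(specificity))


def binormal_auc(d: float) -> float:
    """AUC of two equal-variance normals separated by d: Φ(d/√2)."""
    return float(sps.norm.cdf(d / np.sqrt(2.0)))


def power_two_sample(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test at effect size d (noncentral t)."""
    if d < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need d >= 0 and n >= 2 per group")
    power = TTestIndPower().power(effect_size=d, nobs1=n1, ratio=n2 / n1,
                                  alpha=alpha, alternative="two-sided")
    return float(power)


def run_full_analysis(*args, **kwargs):
    """Study-level analysis over trace tables; see :mod:`silentpupil.pipeline`."""
    from .pipeline import run_full_analysis as _impl
    return _impl(*args, **kwargs)
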
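"""Diagnostic-test evaluation statistics.

Covers the metrics a diagnostic study reports around a confusion table:
accuracy/sensitivity/specificity with Wald (or Clopper-Pearson) binomial
intervals, the diagnostic odds ratio, prevalence-adjusted ("unbiased")
positive predictive value, McNemar's test with Cohen's g for paired
classifier comparisons, the Friedman test and one-sided Wilcoxon
signed-rank post hocs with rank-biserial effect sizes, normal-theory
confidence intervals for mean epoch probabilities, Beta-posterior
credible intervals for per-subject case-epoch proportions, and
Hanley-McNeil AUC-based sample-size computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as st

__all__ = [
    "ConfusionTable", "PrevalenceSpec", "confusion_metrics", "wald_ci",
    "clopper_pearson_ci", "dor", "unbiased_ppv", "mcnemar", "friedman",
    "wilcoxon_one_sided", "mean_prob_ci", "beta_credible_interval",
    "auc_sample_size", "bonferroni",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Subject-level 2x2 confusion counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class PrevalenceSpec:
    """Population disease prevalence, open interval (0, 1)."""

    prevalence: float

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in the open interval (0, 1)")


def confusion_metrics(ct: ConfusionTable, percent: bool = False) -> dict:
    """Accuracy, sensitivity, specificity.

    Undefined ratios (zero denominator) are reported as None rather than
    propagating NaN.
    """
    scale = 100.0 if percent else 1.0

    def ratio(num, den):
        return scale * num / den if den > 0 else None

    return {
        "Acc": ratio(ct.TP + ct.TN, ct.N),
        "Se": ratio(ct.TP, ct.TP + ct.FN),
        "Sp": ratio(ct.TN, ct.TN + ct.FP),
    }


def wald_ci(k: int, n: int, level: float = 0.95):
    """Normal-approximation binomial CI on the percent scale, clipped to
    [0, 100]."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    p = k / n
    z = st.norm.ppf((1 + level) / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return (max(0.0, 100 * (p - half)), min(100.0, 100 * (p + half)))


def clopper_pearson_ci(k: int, n: int, level: float = 0.95):
    """Exact binomial CI (percent scale)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1 - level
    lo = 0.0 if k == 0 else st.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else st.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return (100 * lo, 100 * hi)


def dor(se: float, sp: float) -> dict:
    """Diagnostic odds ratio Se*Sp / ((1-Se)(1-Sp)).

    Returns {"value": float or inf, "infinite": bool}; the ratio is
    infinite when either rate is perfect.
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("Se and Sp must be proportions in [0, 1]")
    if se == 1.0 or sp == 1.0:
        return {"value": math.inf, "infinite": True}
    return {"value": (se * sp) / ((1 - se) * (1 - sp)), "infinite": False}


def unbiased_ppv(se: float, sp: float, prev: PrevalenceSpec) -> float:
    """Prevalence-adjusted positive predictive value (proportion).

    PPV = Se*prev / (Se*prev + (1-prev)(1-Sp)).
    """
    if not (0 <= se <= 1 and 0 <= sp <= 1):
        raise ValueError("Se and Sp must be proportions in [0, 1]")
    p = prev.prevalence
    denom = se * p + (1 - p) * (1 - sp)
    if denom == 0:
        raise ValueError("PPV undefined: no positive test results (Se=0, Sp=1)")
    return se * p / denom


def mcnemar(correct_a, correct_b, mode: str = "exact") -> dict:
    """McNemar's paired-proportion test between two classifiers.

    ``correct_a``/``correct_b`` are per-subject correctness booleans.
    b = a correct & b wrong, c = the reverse.  mode="exact" is the
    two-sided binomial test (small cohorts); mode="chi2" the
    continuity-corrected chi-square.  Cohen's g = |b/(b+c) - 1/2|.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_vec = np.asarray(correct_b, dtype=bool)
    if a.shape != b_vec.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(a & ~b_vec))
    c = int(np.sum(~a & b_vec))
    if b + c == 0:
        return {"p": 1.0, "b": b, "c": c, "cohens_g": None,
                "note": "no discordant pairs; effect size undefined"}
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
    table = [[0, b], [c, 0]]  # only discordant counts matter
    res = sm_mcnemar(table, exact=(mode == "exact"), correction=True)
    return {"p": float(res.pvalue), "b": b, "c": c,
            "cohens_g": abs(b / (b + c) - 0.5)}


def friedman(matrix) -> dict:
    """Friedman chi-square over a (blocks x treatments) matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 rows and >=2 columns")
    constant_rows = int(np.sum(np.ptp(m, axis=1) == 0))
    if constant_rows == m.shape[0]:
        # every block ties all treatments: no evidence either way
        return {"statistic": 0.0, "p": 1.0, "constant_rows": constant_rows}
    stat, p = st.friedmanchisquare(*m.T)
    return {"statistic": float(stat), "p": float(p),
            "constant_rows": constant_rows}


def wilcoxon_one_sided(a, b, alternative: str = "greater") -> dict:
    """One-sided Wilcoxon signed-rank test with rank-biserial effect size.

    Exact p for n <= 30 without ties or zeros, otherwise the
    tie-corrected normal approximation.  rank_biserial =
    (W+ - W-) / (W+ + W-) over the signed ranks of the non-zero
    differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired vectors of length >= 5")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return {"p": None, "rank_biserial": None,
                "note": "all differences zero; test undefined"}
    ranks = st.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    exact = nz.size <= 30 and np.unique(np.abs(nz)).size == nz.size \
        and nz.size == d.size
    res = st.wilcoxon(a, b, alternative=alternative,
                      method="exact" if exact else "approx")
    return {"p": float(res.pvalue),
            "rank_biserial": (w_pos - w_neg) / (w_pos + w_neg),
            "exact": exact}


def bonferroni(p: float, family_size: int = 3) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    return min(1.0, p * family_size)


def mean_prob_ci(probs, level: float = 0.999):
    """Normal-theory CI for a mean probability, clipped to [0, 1]."""
    probs = np.asarray(probs, dtype=float)
    if probs.size < 2:
        raise ValueError("need at least 2 probabilities")
    z = st.norm.ppf((1 + level) / 2)
    mu = probs.mean()
    half = z * probs.std(ddof=1) / math.sqrt(probs.size)
    return (max(0.0, mu - half), min(1.0, mu + half))


def beta_credible_interval(k: int, n: int, prior=(1.0, 1.0),
                           level: float = 0.999):
    """Equal-tailed Beta posterior interval for a binomial proportion.

    Treats the ``k`` of ``n`` epochs predicted as case as Bernoulli draws:
    posterior Beta(prior_a + k, prior_b + n - k).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    a = prior[0] + k
    b = prior[1] + n - k
    alpha = 1 - level
    return (float(st.beta.ppf(alpha / 2, a, b)),
            float(st.beta.ppf(1 - alpha / 2, a, b)))


def _hanley_mcneil_se(auc: float, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n - 1) * (q1 - auc**2)
           + (n - 1) * (q2 - auc**2)) / n**2
    return math.sqrt(var)


def auc_sample_size(auc0: float, auc1: float, alpha: float = 0.05,
                    power: float = 0.95, one_sided: bool = True,
                    n_max: int = 10**6) -> int:
    """Smallest equal-group n for a z-test of AUC against a null value.

    Uses the Hanley-McNeil variance with Q1 = A/(2-A), Q2 = 2A^2/(1+A);
    requires (auc1 - auc0) >= z_alpha SE(auc0, n) + z_beta SE(auc1, n).
    """
    if not 0.5 <= auc0 < auc1 < 1:
        raise ValueError("need 0.5 <= auc0 < auc1 < 1")
    z_a = st.norm.ppf(1 - alpha) if one_sided else st.norm.ppf(1 - alpha / 2)
    z_b = st.norm.ppf(power)
    delta = auc1 - auc0
    for n in range(2, n_max + 1):
        if delta >= z_a * _hanley_mcneil_se(auc0, n) + \
                z_b * _hanley_mcneil_se(auc1, n):
            return n
    raise ValueError(f"power not reachable with n <= {n_max}")
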
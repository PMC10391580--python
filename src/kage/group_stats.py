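"""Statistical testing layer for group comparisons.

Comparisons are normality-gated: a Shapiro-Wilk test on the paired
differences (or on each sample for independent designs) decides between
the parametric t test and its rank-based counterpart.  p values are
adjusted for false discovery rate with Benjamini-Hochberg, applied
independently within each behavioral category.  The module also carries
the exact binomial test against chance and the Wilcoxon signed-rank
sample-size calculation via the asymptotic-relative-efficiency (A.R.E.)
correction of the noncentral-t power formula (normal parent, ARE = 3/pi),
the method used by the G*Power calculator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "compare_paired",
    "compare_independent",
    "adjust_bh",
    "binomial_tail",
    "min_n_wilcoxon_are",
    "wilcoxon_are_power",
    "anova_oneway",
]

ALPHA_NORMALITY = 0.05
ARE_NORMAL = 3.0 / np.pi


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    p_adjusted: float | None = None
    p_normality: float | None = None
    n: tuple = ()
    direction: int = 0          # sign of the effect (post - pre / b - a)
    zero_variance: bool = False

    def __post_init__(self):
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p outside [0, 1]: {self.p}")


def compare_paired(x_pre, x_post) -> StatResult:
    """Paired comparison with a Shapiro-Wilk gate on the differences.

    Differences that pass the normality gate (p >= 0.05) go to the paired
    t test; otherwise the exact two-tailed Wilcoxon signed-rank test is
    used (zero differences dropped, exact null for n <= 25).
    """
    x_pre = np.asarray(x_pre, float)
    x_post = np.asarray(x_post, float)
    if x_pre.shape != x_post.shape:
        raise ValueError("paired samples must have equal length")
    n = len(x_pre)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    d = x_post - x_pre
    direction = int(np.sign(np.mean(d))) if np.any(d) else 0
    if np.allclose(d, d[0]):
        if np.allclose(d, 0.0):
            return StatResult("paired_t", 0.0, 1.0, n=(n,),
                              direction=0, zero_variance=True)
        return StatResult("paired_t", np.inf * np.sign(d[0]), 0.0,
                          n=(n,), direction=int(np.sign(d[0])),
                          zero_variance=True)
    p_norm = float(stats.shapiro(d).pvalue)
    if p_norm >= ALPHA_NORMALITY:
        t, p = stats.ttest_rel(x_post, x_pre)
        return StatResult("paired_t", float(t), float(p),
                          p_normality=p_norm, n=(n,), direction=direction)
    nz = d[d != 0]
    mode = "exact" if len(nz) <= 25 else "approx"
    w, p = stats.wilcoxon(nz, mode=mode, correction=(mode == "approx"))
    return StatResult("wilcoxon_signed_rank", float(w), float(p),
                      p_normality=p_norm, n=(n,), direction=direction)


def compare_independent(a, b, pooled: bool = False) -> StatResult:
    """Independent two-sample comparison (Welch by default)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    direction = int(np.sign(np.mean(b) - np.mean(a)))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        return StatResult("student_t", 0.0 if p == 1.0 else np.inf, p,
                          n=(len(a), len(b)), direction=direction,
                          zero_variance=True)
    p_norm = float(min(
        stats.shapiro(a).pvalue if np.ptp(a) > 0 else 1.0,
        stats.shapiro(b).pvalue if np.ptp(b) > 0 else 1.0))
    if p_norm >= ALPHA_NORMALITY:
        t, p = stats.ttest_ind(b, a, equal_var=pooled)
        name = "student_t" if pooled else "welch_t"
        return StatResult(name, float(t), float(p), p_normality=p_norm,
                          n=(len(a), len(b)), direction=direction)
    u, p = stats.mannwhitneyu(b, a, alternative="two-sided")
    return StatResult("mann_whitney", float(u), float(p),
                      p_normality=p_norm, n=(len(a), len(b)),
                      direction=direction)


def adjust_bh(pvals_by_category: dict) -> dict:
    """Step-up Benjamini-Hochberg within each behavioral category.

    ``pvals_by_category`` maps category -> sequence of raw p values;
    returns the same mapping with adjusted values (monotone, capped at 1).
    """
    out = {}
    for cat, ps in pvals_by_category.items():
        ps = np.asarray(ps, float)
        if np.any((ps < 0) | (ps > 1)):
            raise ValueError(f"p values outside [0, 1] in category {cat!r}")
        if len(ps) == 0:
            out[cat] = ps
            continue
        out[cat] = multipletests(ps, method="fdr_bh")[1]
    return out


def binomial_tail(k: int, n: int, p0: float = 0.5,
                  alternative: str = "greater") -> float:
    """Exact binomial tail probability of k successes in n trials.

    Two-sided p sums all outcomes whose probability does not exceed that
    of the observed count.
    """
    if k > n:
        raise ValueError("k cannot exceed n")
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)


def wilcoxon_are_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-tailed one-sample Wilcoxon signed-rank test at
    effect size ``d``, by the A.R.E.-corrected noncentral-t approximation.

    The test is treated as a one-sample t test on an effective sample of
    ``n * 3/pi`` observations (the Wilcoxon-vs-t efficiency under a normal
    parent): df = n*ARE - 1, noncentrality d*sqrt(n*ARE).
    """
    n_eff = n * ARE_NORMAL
    df = n_eff - 1.0
    if df <= 0:
        return 0.0
    nc = d * np.sqrt(n_eff)
    t_crit = stats.t.isf(alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


def min_n_wilcoxon_are(d: float, alpha: float = 0.05, power: float = 0.8,
                       n_max: int = 10**6) -> int:
    """Smallest n with A.R.E.-approximated Wilcoxon power >= target."""
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    lo, hi = 2, 2
    while wilcoxon_are_power(hi, d, alpha) < power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(f"power {power} unattainable within n <= {n_max}")
    while lo < hi:  # power is monotone in n; binary search for the minimum
        mid = (lo + hi) // 2
        if wilcoxon_are_power(mid, d, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def anova_oneway(groups) -> StatResult:
    """Classical one-way F test across two or more groups."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        return StatResult("anova_oneway", 0.0, 1.0,
                          n=tuple(len(g) for g in groups),
                          zero_variance=True)
    f, p = stats.f_oneway(*groups)
    return StatResult("anova_oneway", float(f), float(p),
                      n=tuple(len(g) for g in groups))
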
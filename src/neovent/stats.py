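"""Group-comparison statistical engine.

Thin, explicit wrappers around the scipy/statsmodels routines the study
design calls for — Mann-Whitney U (exact for small samples, tie- and
continuity-corrected normal approximation otherwise), Welch's t,
one-way ANOVA / Kruskal-Wallis with a Student-Newman-Keuls stepwise range
post-hoc, chi-squared/Fisher for 2x2 tables, and the two-sample t-test
sample-size solve.  The SNK procedure is implemented here (no installed
package provides it) on scipy's studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower


def summarize_group(values) -> tuple[float, float, int]:
    """(median, IQR, n) with linear-interpolation quantiles."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1), int(x.size)


def mann_whitney_u(a, b, exact_max_n: int = 16) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U for the first sample, p).

    Uses the exact null distribution when the combined sample is small
    (``n_a + n_b <= exact_max_n``) and there are no ties; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank alternative to the independent comparison."""
    res = sps.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def welch_t(a, b, pooled: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test: (t, df, p).  Welch by default, pooled by flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both groups")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class PosthocDecision:
    group_i: int
    group_j: int
    q: float
    q_crit: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    statistic: float       # F (parametric) or tie-corrected H (ranks)
    p_value: float
    method: str            # "anova" | "kruskal"
    posthoc: list[PosthocDecision]


from functools import lru_cache


@lru_cache(maxsize=512)
def _q_crit(alpha: float, span: int, df: float) -> float:
    # studentized_range.ppf is expensive; cache per (alpha, span, df)
    return float(sps.studentized_range.ppf(1.0 - alpha, span, df))


def _snk(means: np.ndarray, ns: np.ndarray, ms_within: float, df_within: float,
         alpha: float) -> list[PosthocDecision]:
    """Student-Newman-Keuls stepwise range procedure.

    Groups are ordered by mean; a stretch of p ordered groups is tested with
    the studentized-range critical value q(alpha, p, df); non-significant
    stretches shield their sub-stretches (the classic non-testing rule).
    Unequal n handled with the harmonic mean of the pair being compared.
    """
    order = np.argsort(means)
    k = len(means)
    decisions: dict[tuple[int, int], PosthocDecision] = {}
    shielded: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        q_crit = _q_crit(alpha, span, float(df_within))
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            i, j = order[lo], order[hi]
            if (lo, hi) in shielded:
                sig = False
                q_obs = np.nan
            else:
                n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
                se = np.sqrt(ms_within / n_h)
                q_obs = float((means[j] - means[i]) / se) if se > 0 else 0.0
                sig = q_obs > q_crit
            if not sig:
                for a in range(lo, hi + 1):
                    for b in range(a + 1, hi + 1):
                        shielded.add((a, b))
            decisions[(int(i), int(j))] = PosthocDecision(
                int(i), int(j), q_obs, q_crit, bool(sig))
    return [decisions[key] for key in sorted(decisions)]


def anova_on_ranks_with_posthoc(groups, parametric: bool = True,
                                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA (or Kruskal-Wallis on ranks) with an SNK post-hoc.

    Parametric path: F statistic on raw data, SNK on group means with the
    within-group mean square.  Nonparametric path: tie-corrected
    Kruskal-Wallis H, with the same SNK machinery applied to the
    rank-transformed data (SNK on mean ranks).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ns = np.array([g.size for g in groups], dtype=float)
    if parametric:
        f, p = sps.f_oneway(*groups)
        data = groups
        method = "anova"
        stat = float(f)
    else:
        h, p = sps.kruskal(*groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        data, start = [], 0
        for g in groups:
            data.append(ranks[start:start + g.size])
            start += g.size
        method = "kruskal"
        stat = float(h)
    means = np.array([d.mean() for d in data])
    n_total = int(ns.sum())
    df_within = n_total - len(groups)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    if np.isnan(stat):  # all groups identical: no variance anywhere
        stat, p = 0.0, 1.0
    posthoc = ([] if ms_within == 0.0
               else _snk(means, ns, ms_within, df_within, alpha))
    return AnovaResult(statistic=stat, p_value=float(p), method=method,
                       posthoc=posthoc)


def categorical_test(table) -> tuple[float, float, str]:
    """2x2 association test: chi-squared with Yates correction when every
    expected count exceeds 5, otherwise Fisher's exact (two-sided).  Returns
    (statistic, p, method); the Fisher statistic is the odds ratio."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    expected = sps.contingency.expected_freq(t)
    if (expected > 5).all():
        chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
        return float(chi2), float(p), "chi-squared (Yates)"
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p), "fisher"


def required_sample_size(delta: float, sd: float, power: float = 0.8,
                         alpha: float = 0.05) -> int:
    """Smallest per-group n giving a two-sample t-test the target power.

    Solves the exact (noncentral-t) power equation; the classic normal
    approximation ``n0 = 2 sigma^2 (z_{1-a/2} + z_power)^2 / delta^2``
    seeds the solver.
    """
    if not (delta > 0 and sd > 0):
        raise ValueError("delta and sd must be > 0")
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    effect = delta / sd
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # solver warns in degenerate corners
            n = TTestIndPower().solve_power(effect_size=effect, alpha=alpha,
                                            power=power, ratio=1.0,
                                            alternative="two-sided")
        n = float(np.atleast_1d(n)[0])
    except Exception:
        n = np.nan
    if not np.isfinite(n):  # solver can fail when even n=2 over-powers
        n = 2.0
    n_int = max(2, int(np.ceil(n - 1e-9)))
    # verify against the exact noncentral-t power and adjust to the
    # smallest integer n that actually reaches the target
    while n_int > 2 and two_sample_t_power(n_int - 1, delta, sd, alpha) >= power:
        n_int -= 1
    while two_sample_t_power(n_int, delta, sd, alpha) < power:
        n_int += 1
    return n_int


def two_sample_t_power(n: int, delta: float, sd: float,
                       alpha: float = 0.05) -> float:
    """Exact two-sided power of the equal-n two-sample t-test (noncentral t)."""
    df = 2 * n - 2
    nc = (delta / sd) * np.sqrt(n / 2.0)
    crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))


def normal_approx_sample_size(delta: float, sd: float, power: float = 0.8,
                              alpha: float = 0.05) -> float:
    """The z-based starting value for :func:`required_sample_size` (fractional)."""
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    return float(2.0 * (sd / delta) ** 2 * (z_a + z_b) ** 2)
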
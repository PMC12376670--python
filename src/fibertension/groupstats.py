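"""Cohort-level statistics with a normality-gated choice of test.

Patient-level summaries (one value per patient, each patient's fields
averaged beforehand) are compared with the scheme common in quantitative
histology: normality is assessed by a panel of four tests (D'Agostino-
Pearson, Anderson-Darling, Shapiro-Wilk, Kolmogorov-Smirnov/Lilliefors);
normally distributed groups get a t test (two groups) or one-way ANOVA with
Tukey's HSD (more), otherwise Mann-Whitney or Kruskal-Wallis with Dunn's
post-hoc. Proximity profiles are compared by a two-way ANOVA over group x
distance-bin, declining profiles by a linear-contrast test for trend, and
pixel-fraction co-occurrence by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors, normal_ad

__all__ = [
    "GroupSample",
    "TestResult",
    "assess_normality",
    "compare_groups",
    "profile_anova",
    "trend_test",
    "pearson_correlation",
]

ALPHA = 0.05


@dataclass
class GroupSample:
    """Per-patient scalar summaries for one group (label + values)."""

    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    posthoc: list[tuple[tuple[str, str], float]] | None = None
    r: float | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


def _normality_pvalues(values: np.ndarray) -> dict[str, float]:
    """p-values of the four normality tests applicable at this sample size."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    out: dict[str, float] = {}
    if n >= 3:
        out["shapiro_wilk"] = float(stats.shapiro(values).pvalue)
    if n >= 4:
        out["anderson_darling"] = float(normal_ad(values)[1])
        out["kolmogorov_smirnov"] = float(lilliefors(values, dist="norm")[1])
    if n >= 8:  # skew+kurtosis omnibus needs a minimally informative sample
        out["dagostino_pearson"] = float(stats.normaltest(values).pvalue)
    return out


def assess_normality(values: np.ndarray, alpha: float = ALPHA) -> str:
    """Gate a sample as ``"parametric"`` or ``"nonparametric"``.

    Runs the applicable normality tests at ``alpha`` and calls the sample
    parametric iff at least 3 of them fail to reject normality. A sample too
    small for 3 tests to apply (n < 4) can never clear that bar and is
    treated as nonparametric, as are constant samples.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 3 or np.ptp(values) == 0:
        return "nonparametric"
    pvals = _normality_pvalues(values)
    non_reject = sum(p > alpha for p in pvals.values())
    return "parametric" if non_reject >= 3 else "nonparametric"


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def _dunn_posthoc(groups: list[GroupSample]) -> list[tuple[tuple[str, str], float]]:
    """Dunn's rank-based pairwise z tests with Bonferroni adjustment."""
    pooled = np.concatenate([g.values for g in groups])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        stop = start + g.values.size
        mean_ranks.append(ranks[start:stop].mean())
        sizes.append(g.values.size)
        start = stop
    k = len(groups)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            out.append(((groups[i].group_label, groups[j].group_label), min(1.0, p * m)))
    return out


def compare_groups(groups: list[GroupSample], welch: bool = True) -> TestResult:
    """Normality-gated comparison of two or more groups.

    Parametric (every group passes the normality gate): two-tailed unpaired
    t test (Welch by default) for k = 2, one-way ANOVA with Tukey's HSD for
    k > 2. Nonparametric: Mann-Whitney (asymptotic, two-sided, no continuity
    correction so perfectly tied identical samples give p = 1) for k = 2,
    Kruskal-Wallis with Dunn's post-hoc for k > 2.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.group_label!r} has n < 2")
    parametric = all(assess_normality(g.values) == "parametric" for g in groups)
    arrays = [g.values for g in groups]
    if len(groups) == 2:
        if parametric:
            res = stats.ttest_ind(*arrays, equal_var=not welch)
            return TestResult("welch_t" if welch else "student_t",
                              float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(*arrays, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        return TestResult("mann_whitney", float(res.statistic), float(res.pvalue))
    if parametric:
        res = stats.f_oneway(*arrays)
        hsd = stats.tukey_hsd(*arrays)
        posthoc = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                posthoc.append(((groups[i].group_label, groups[j].group_label),
                                float(hsd.pvalue[i, j])))
        return TestResult("anova_tukey", float(res.statistic), float(res.pvalue), posthoc)
    res = stats.kruskal(*arrays)
    return TestResult("kruskal_dunn", float(res.statistic), float(res.pvalue),
                      _dunn_posthoc(groups))


# ---------------------------------------------------------------------------
# Profile comparisons
# ---------------------------------------------------------------------------


def profile_anova(profiles_by_group: dict[str, np.ndarray]) -> TestResult:
    """Two-way ANOVA (group x distance-bin) on per-sample bin fractions.

    Each group's entry is an array of shape ``(n_samples, n_bins)`` with one
    proximity-profile fraction row per sample; all groups must share binning.
    The reported p is the group main effect; Tukey's HSD on the per-sample
    bin-marginal means serves as the post-hoc.
    """
    labels = list(profiles_by_group)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    mats = [np.atleast_2d(np.asarray(profiles_by_group[g], dtype=np.float64)) for g in labels]
    n_bins = {m.shape[1] for m in mats}
    if len(n_bins) != 1:
        raise ValueError("mismatched profile binning across groups")
    (n_bins,) = n_bins

    # balanced two-way layout: cells are (group, bin), replicates are samples
    grand = np.mean([m.mean() for m in mats])
    ss_group = ss_err = 0.0
    for m in mats:
        cell_means = m.mean(axis=0)
        ss_group += m.shape[0] * n_bins * (m.mean() - grand) ** 2
        ss_err += np.sum((m - cell_means) ** 2)
    df_group = len(labels) - 1
    df_err = sum((m.shape[0] - 1) * n_bins for m in mats)
    if ss_group < 1e-12:
        p_group, f_group = 1.0, 0.0
    elif ss_err <= 0 or df_err <= 0:
        p_group, f_group = 0.0, float("inf")
    else:
        ms_group = ss_group / df_group
        ms_err = ss_err / df_err
        f_group = ms_group / ms_err
        p_group = float(stats.f.sf(f_group, df_group, df_err))

    marginals = [GroupSample(g, m.mean(axis=1)) for g, m in zip(labels, mats)]
    posthoc = None
    if all(m.values.size >= 2 for m in marginals) and ss_group >= 1e-12:
        hsd = stats.tukey_hsd(*[m.values for m in marginals])
        posthoc = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                posthoc.append(((labels[i], labels[j]), float(hsd.pvalue[i, j])))
    return TestResult("two_way_anova_group_x_bin", float(f_group), p_group, posthoc)


def trend_test(profile_values: np.ndarray) -> TestResult:
    """One-way-ANOVA linear-contrast test for trend across ordered bins.

    ``profile_values`` has shape ``(n_samples, n_bins)`` with bins in
    increasing distance order. Contrast coefficients are the centered bin
    ranks; the p-value comes from the contrast F on (1, df_error). The
    statistic reported is the contrast estimate (slope-like; exactly 0 for a
    perfectly flat profile).
    """
    y = np.atleast_2d(np.asarray(profile_values, dtype=np.float64))
    n_samples, n_bins = y.shape
    if n_bins < 3:
        raise ValueError("need >=3 ordered bins")
    if n_samples < 2:
        raise ValueError("need >=2 samples per bin")
    coeffs = np.arange(n_bins, dtype=np.float64) - (n_bins - 1) / 2.0
    bin_means = y.mean(axis=0)
    contrast = float(np.dot(coeffs, bin_means))
    ss_contrast = contrast**2 / np.sum(coeffs**2 / n_samples)
    ss_err = np.sum((y - bin_means) ** 2)
    df_err = n_bins * (n_samples - 1)
    if ss_err <= 0:
        p = 1.0 if abs(contrast) < 1e-12 else 0.0
    else:
        f = ss_contrast / (ss_err / df_err)
        p = float(stats.f.sf(f, 1, df_err))
    return TestResult("anova_trend_contrast", contrast, p)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson product-moment correlation with the two-sided t-transform p."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    res = stats.pearsonr(x, y)
    return TestResult("pearson", float(res.statistic), float(res.pvalue), r=float(res.statistic))
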
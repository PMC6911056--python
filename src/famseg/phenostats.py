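"""Genotype-stratified and case-control phenotype statistics.

Group comparisons follow a normality-gated routing: Shapiro-Wilk is run
per group at alpha = 0.05 and the headline test is parametric (one-way
ANOVA / unpaired t-test) when every group passes, non-parametric
(Kruskal-Wallis / Wilcoxon rank-sum) otherwise.  Both routes are always
computed so the gate only selects which result leads.

Also provided: one-way ANOVA from printed summary statistics (n, mean,
SD) for published tables whose raw data are unavailable, Bonferroni
correction, covariate adjustment of FeNO / exacerbation frequency as the
ratio of actual to model-predicted values, percent bronchodilator
responsiveness, and odor-threshold group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "shapiro_wilk",
    "anova_oneway",
    "anova_from_summary",
    "kruskal_wallis",
    "two_group_test",
    "bonferroni",
    "bonferroni_adjust",
    "covariate_adjust",
    "bdr_percent",
    "odor_group_comparison",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group summary statistics (n, mean, SD)."""

    group_label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group_label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.group_label!r}: negative SD")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str  # anova | kruskal_wallis | t_test | wilcoxon | shapiro_wilk
    statistic: float
    df: tuple[float, ...] | None
    p: float
    normality_route: str | None = None  # parametric | nonparametric
    n_per_group: tuple[int, ...] | None = None
    degenerate: bool = False
    companion: "TestResult | None" = field(default=None, repr=False)


def _check_groups(groups: Sequence[Sequence[float]], min_n: int = 2) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < min_n:
            raise ValueError(f"group {i} has n={len(g)} < {min_n}")
        if not np.isfinite(g).all():
            raise ValueError(f"group {i} contains non-finite values")
    return arrs


def shapiro_wilk(sample: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (Royston's p-value approximation).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = stats.shapiro(x)
    return TestResult(test_name="shapiro_wilk", statistic=float(w),
                      df=None, p=float(p), n_per_group=(len(x),))


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MSB/MSW on (k-1, N-k) df."""
    arrs = _check_groups(groups)
    if all(np.ptp(g) == 0 for g in arrs):
        means = [g[0] for g in arrs]
        if len(set(means)) > 1:
            raise ValueError("zero within-group variance with unequal means")
    f, p = stats.f_oneway(*arrs)
    k = len(arrs)
    n_total = sum(len(g) for g in arrs)
    return TestResult(test_name="anova", statistic=float(f),
                      df=(k - 1, n_total - k), p=float(p),
                      normality_route="parametric",
                      n_per_group=tuple(len(g) for g in arrs))


def anova_from_summary(summaries: Sequence[GroupSummary]) -> TestResult:
    """One-way ANOVA computed from per-group (n, mean, SD) only.

    SSB = sum n_i (m_i - grand_mean)^2 with the n-weighted grand mean;
    SSW = sum (n_i - 1) s_i^2; F = (SSB/(k-1)) / (SSW/(N-k)) and p from
    the F(k-1, N-k) distribution.  Identical to :func:`anova_oneway` on
    any raw data matching those moments.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    k = len(summaries)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds ** 2).sum()
    df = (k - 1, n_total - k)
    if ssw == 0:
        if ssb == 0:
            return TestResult("anova", statistic=0.0, df=df, p=1.0,
                              normality_route="parametric",
                              n_per_group=tuple(int(n) for n in ns),
                              degenerate=True)
        return TestResult("anova", statistic=float("inf"), df=df, p=0.0,
                          normality_route="parametric",
                          n_per_group=tuple(int(n) for n in ns),
                          degenerate=True)
    f = (ssb / df[0]) / (ssw / df[1])
    p = float(stats.f.sf(f, df[0], df[1]))
    return TestResult("anova", statistic=float(f), df=df, p=p,
                      normality_route="parametric",
                      n_per_group=tuple(int(n) for n in ns))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; asymptotic chi-square p."""
    arrs = _check_groups(groups, min_n=1)
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: ranks degenerate")
    h, p = stats.kruskal(*arrs)
    return TestResult("kruskal_wallis", statistic=float(h),
                      df=(len(arrs) - 1,), p=float(p),
                      normality_route="nonparametric",
                      n_per_group=tuple(len(g) for g in arrs))


def two_group_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Normality-gated two-group comparison.

    Both the unpaired t-test and the Wilcoxon rank-sum (Mann-Whitney U,
    two-sided, normal approximation with tie correction) are computed; the
    headline result follows the Shapiro-Wilk gate (both groups normal at
    alpha=0.05 -> t-test), with the other attached as ``companion``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")

    def normal(g: np.ndarray) -> bool:
        if len(g) < 3 or np.ptp(g) == 0:
            return False
        return stats.shapiro(g)[1] > NORMALITY_ALPHA

    t_stat, t_p = stats.ttest_ind(x, y)
    t_res = TestResult("t_test", statistic=float(t_stat),
                       df=(len(x) + len(y) - 2,), p=float(t_p),
                       normality_route="parametric",
                       n_per_group=(len(x), len(y)))
    u_stat, u_p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
    w_res = TestResult("wilcoxon", statistic=float(u_stat), df=None,
                       p=float(u_p), normality_route="nonparametric",
                       n_per_group=(len(x), len(y)))
    if normal(x) and normal(y):
        t_res.companion = w_res
        return t_res
    w_res.companion = t_res
    return w_res


def bonferroni(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


def covariate_adjust(table: pd.DataFrame, value_field: str,
                     covariates: Sequence[str] = ("age", "sex", "height"),
                     ) -> pd.Series:
    """Ratio of actual to covariate-predicted phenotype values.

    A single pooled least-squares linear model of ``value_field`` on the
    covariates (with intercept; a ``sex`` column may be 'male'/'female' or
    already numeric) is fitted over all complete rows; the returned series
    holds actual/predicted per row, NaN where the value or a covariate is
    missing.  A constant (or collinear) covariate raises, naming it.
    """
    missing_cols = [c for c in (value_field, *covariates)
                    if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing column(s): {missing_cols}")
    df = table[[value_field, *covariates]].copy()
    if "sex" in covariates and df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"male": 0, "female": 1, "M": 0, "F": 1})
    df = df.apply(pd.to_numeric, errors="coerce")
    complete = df.dropna()
    p = len(covariates)
    if len(complete) < p + 2:
        raise ValueError(
            f"need >= {p + 2} complete rows for {p} covariates, "
            f"have {len(complete)}")
    for c in covariates:
        if complete[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    X = np.column_stack([np.ones(len(complete)),
                         complete[list(covariates)].to_numpy(float)])
    y = complete[value_field].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design over covariates {tuple(covariates)}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    predicted = X @ beta
    ratio = pd.Series(np.nan, index=table.index, dtype=float)
    ratio.loc[complete.index] = y / predicted
    return ratio


def bdr_percent(pre_value: float, post_value: float) -> float:
    """Percent bronchodilator responsiveness: 100*(post - pre)/pre."""
    if pre_value <= 0:
        raise ValueError("pre-bronchodilator value must be > 0")
    return 100.0 * (post_value - pre_value) / pre_value


def odor_group_comparison(table: pd.DataFrame, group_field: str,
                          value_field: str = "odor_score_pea",
                          ) -> tuple[TestResult, pd.DataFrame]:
    """Compare odor-threshold scores between groups.

    Two groups route through :func:`two_group_test`; three or more use the
    Shapiro-Wilk gate to pick ANOVA or Kruskal-Wallis (both computed).
    Returns the headline test and a per-group table of n, mean and SEM.
    """
    if group_field not in table.columns or value_field not in table.columns:
        raise ValueError("missing group or value column")
    groups = {k: v[value_field].dropna().to_numpy(float)
              for k, v in table.groupby(group_field, sort=True)}
    groups = {k: g for k, g in groups.items() if len(g) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 scores each")
    labels = list(groups)
    arrs = [groups[k] for k in labels]
    summary = pd.DataFrame({
        "group": labels,
        "n": [len(g) for g in arrs],
        "mean": [g.mean() for g in arrs],
        "sem": [g.std(ddof=1) / np.sqrt(len(g)) for g in arrs],
    })
    if len(arrs) == 2:
        return two_group_test(arrs[0], arrs[1]), summary

    def normal(g: np.ndarray) -> bool:
        return len(g) >= 3 and np.ptp(g) > 0 and \
            stats.shapiro(g)[1] > NORMALITY_ALPHA

    a_res = anova_oneway(arrs)
    k_res = kruskal_wallis(arrs)
    if all(normal(g) for g in arrs):
        a_res.companion = k_res
        return a_res, summary
    k_res.companion = a_res
    return k_res, summary
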
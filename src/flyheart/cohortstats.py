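"""Cohort statistics: group comparisons and age trends of per-fly metrics.

Group comparisons use the non-parametric two-sided Wilcoxon rank-sum test
with the conventional star notation (* p < 5e-2, ** p < 5e-3).  Age trends
are ordinary least squares of a metric on age over per-fly records with
age >= 10 days, and pairs of trends are compared with Zar's two-slope test:
with pooled residual variance

    s^2 = (RSS_a + RSS_b) / (n_a + n_b - 4)

the statistic t = (b_a - b_b) / sqrt(s^2/Sxx_a + s^2/Sxx_b) follows a t
distribution with n_a + n_b - 4 degrees of freedom under equal slopes.

Fits are over individual fly values by default (more degrees of freedom);
``means=True`` fits per-age group means instead.  No multiple-testing
correction is applied by default (raw p-values with stars); a
Benjamini-Hochberg helper is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LinearFit",
    "SlopeComparison",
    "wilcoxon_compare",
    "stars",
    "fit_age_trend",
    "compare_slopes",
    "summarize_cohort",
    "benjamini_hochberg",
    "MIN_AGE_DAYS",
]

#: Trend analyses are restricted to ages >= 10 days by default.
MIN_AGE_DAYS = 10

#: Largest combined sample size for which the exact rank-sum null is used.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of a metric on age with the sufficient statistics for Zar's test."""

    slope: float
    intercept: float
    slope_se: float
    rss: float          # residual sum of squares
    sxx: float          # sum of squared age deviations
    n: int
    metric: str = ""
    condition: str = ""


@dataclass(frozen=True)
class SlopeComparison:
    slope_a: float
    slope_b: float
    se_diff: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def stars(p: float) -> str:
    """Significance stars: '**' for p < 5e-3, '*' for p < 5e-2, '' otherwise."""
    if p < 5e-3:
        return "**"
    if p < 5e-2:
        return "*"
    return ""


def wilcoxon_compare(values_a, values_b) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Uses exact null enumeration when the combined sample is small
    (n_a + n_b <= 12) and tie-free, and the normal approximation with
    midranks, tie correction and continuity correction otherwise.  Returns
    ``(rank_sum_a, p_value, stars)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")

    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = min(float(res.pvalue), 1.0)

    # report the classical rank-sum of group a: W = U_a + n_a(n_a+1)/2
    w_a = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w_a, p, stars(p)


# ---------------------------------------------------------------------------
# Age trends
# ---------------------------------------------------------------------------

def fit_age_trend(
    records,
    metric: str,
    *,
    min_age: int = MIN_AGE_DAYS,
    condition: str | None = None,
    means: bool = False,
) -> LinearFit:
    """OLS of ``metric`` on ``age_days`` over fly records with age >= min_age.

    ``records`` is a DataFrame with at least ``age_days`` and the metric
    column (plus ``condition`` when filtering).  ``means=True`` collapses to
    per-age group means before fitting.  Requires >= 2 distinct ages and
    >= 3 records after filtering.
    """
    df = records
    if condition is not None:
        df = df[df["condition"] == condition]
    df = df[df["age_days"] >= min_age]
    df = df[np.isfinite(df[metric].astype(float))]
    if means:
        df = df.groupby("age_days", as_index=False)[metric].mean()

    x = df["age_days"].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(
            f"degenerate design for {metric!r}: need >= 2 distinct ages >= {min_age}"
        )
    if x.size < 3:
        raise ValueError(f"need >= 3 records to fit {metric!r}, got {x.size}")

    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    slope_se = math.sqrt(rss / (x.size - 2) / sxx) if x.size > 2 else math.nan
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        rss=rss,
        sxx=sxx,
        n=int(x.size),
        metric=metric,
        condition=condition or "",
    )


def compare_slopes(fit_a: LinearFit, fit_b: LinearFit) -> SlopeComparison:
    """Zar's two-slope t-test with pooled residual variance.

    Degenerate inputs (zero pooled residual variance) give t = 0, p = 1 for
    equal slopes and p = 0 with the ``degenerate`` flag for unequal ones.
    """
    df = fit_a.n + fit_b.n - 4
    if df < 1:
        raise ValueError(f"combined df = {df} < 1; need more records")

    s2 = (fit_a.rss + fit_b.rss) / df
    diff = fit_a.slope - fit_b.slope
    se = math.sqrt(s2 / fit_a.sxx + s2 / fit_b.sxx) if s2 > 0 else 0.0
    # zero pooled variance up to rounding of exactly collinear inputs
    scale = max(abs(fit_a.slope), abs(fit_b.slope), 1.0)
    if se <= 1e-12 * scale:
        if abs(diff) <= 1e-12 * scale:
            return SlopeComparison(fit_a.slope, fit_b.slope, se, 0.0, df, 1.0)
        return SlopeComparison(
            fit_a.slope, fit_b.slope, se, math.copysign(math.inf, diff), df, 0.0,
            degenerate=True,
        )
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return SlopeComparison(fit_a.slope, fit_b.slope, se, t, df, min(p, 1.0))


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(records, metrics=("hp_ms", "ai", "edd_um"), control: str | None = None):
    """Per-condition/per-age mean +- SEM tables and pairwise Wilcoxon tests.

    Returns ``(summary, tests)`` DataFrames.  ``summary`` has one row per
    (condition, age, metric) with n, mean and SEM (NaN and flagged when
    n < 2).  ``tests`` holds, per metric, each condition-vs-control
    comparison at matched age (when ``control`` is given) and each
    successive-age comparison within condition.
    """
    import pandas as pd

    metrics = [m for m in metrics if m in records.columns]
    summary_rows = []
    for (cond, age), grp in records.groupby(["condition", "age_days"], sort=True):
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            n = vals.size
            summary_rows.append(
                {
                    "condition": cond,
                    "age_days": age,
                    "metric": metric,
                    "n": n,
                    "mean": vals.mean() if n else math.nan,
                    "sem": stats.sem(vals, ddof=1) if n > 1 else math.nan,
                    "flag": "" if n > 1 else "sem undefined (n < 2)",
                }
            )
    summary = pd.DataFrame(summary_rows)

    test_rows = []

    def _vals(cond, age, metric):
        sel = records[(records["condition"] == cond) & (records["age_days"] == age)]
        v = sel[metric].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    conditions = sorted(records["condition"].unique())
    ages = sorted(records["age_days"].unique())
    for metric in metrics:
        # successive ages within condition
        for cond in conditions:
            for a0, a1 in zip(ages, ages[1:]):
                va, vb = _vals(cond, a0, metric), _vals(cond, a1, metric)
                if va.size and vb.size:
                    w, p, st = wilcoxon_compare(va, vb)
                    test_rows.append(
                        {
                            "metric": metric,
                            "comparison": "successive_ages",
                            "condition": cond,
                            "group_a": f"{a0}d",
                            "group_b": f"{a1}d",
                            "statistic": w,
                            "p_value": p,
                            "stars": st,
                        }
                    )
        # condition vs control at matched age
        if control is not None:
            for cond in conditions:
                if cond == control:
                    continue
                for age in ages:
                    va, vb = _vals(cond, age, metric), _vals(control, age, metric)
                    if va.size and vb.size:
                        w, p, st = wilcoxon_compare(va, vb)
                        test_rows.append(
                            {
                                "metric": metric,
                                "comparison": "vs_control",
                                "condition": cond,
                                "group_a": f"{cond}@{age}d",
                                "group_b": f"{control}@{age}d",
                                "statistic": w,
                                "p_value": p,
                                "stars": st,
                            }
                        )
    tests = pd.DataFrame(test_rows)
    return summary, tests


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in reports)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
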
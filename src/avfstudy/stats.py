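"""Group summaries, hypothesis tests and correlations for study time-courses.

The statistical layer mirrors classical small-animal study practice: groups
are reported as mean +/- SE (n); two-group comparisons use the unpaired
two-tailed t-test (pooled variance by default, Welch behind a flag); with
three or more groups a variance-equality gate (Levene, center = median)
selects either one-way ANOVA (variances equal) or pairwise Mann-Whitney
tests against baseline (variances unequal); trends are quantified with
Pearson correlation and simple least-squares regression.  Correlations
between time-courses are computed on per-day group means, so n is the
number of shared study days.  No multiple-testing correction is applied by
default (a Holm option exists for sensitivity analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationResult",
    "summarize",
    "ttest_baseline",
    "compare_multi",
    "pearson_corr",
    "correlate_timecourses",
    "timecourse_summary",
    "holm_adjust",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SE summary of one group; SE is NaN (flagged) when n == 1."""

    n: int
    mean: float
    se: float
    se_defined: bool = True


@dataclass(frozen=True)
class TestResult:
    comparison: str
    method: str  # t_test | anova | mann_whitney
    statistic: float
    p_value: float
    variance_gate_p: float = float("nan")
    pairwise: tuple = field(default=())


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    n: int
    r: float
    p_value: float
    slope: float = float("nan")
    intercept: float = float("nan")


def summarize(values) -> GroupSummary:
    """Mean and standard error of one group of replicate measurements."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if x.size == 1:
        return GroupSummary(n=1, mean=float(x[0]), se=float("nan"), se_defined=False)
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        se=float(x.std(ddof=1) / math.sqrt(x.size)),
    )


def _as_group(values, name):
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"group {name!r} needs n >= 2, got {x.size}")
    return x


def ttest_baseline(group, baseline, welch: bool = False,
                   comparison: str = "group_vs_baseline") -> TestResult:
    """Unpaired two-tailed t-test of a group against its baseline group.

    Pooled-variance by default (the classical unpaired t-test); Welch's
    unequal-variance form with ``welch=True``.
    """
    g = _as_group(group, "group")
    b = _as_group(baseline, "baseline")
    if g.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: scipy returns NaN; the comparison is still well defined
        if g.mean() == b.mean():
            return TestResult(comparison, "t_test", 0.0, 1.0)
        return TestResult(comparison, "t_test", math.inf, 0.0)
    t, p = sps.ttest_ind(g, b, equal_var=not welch)
    return TestResult(comparison, "t_test", float(t), float(p))


def compare_multi(groups, labels=None, gate_alpha: float = DEFAULT_ALPHA,
                  comparison: str = "multi_group") -> TestResult:
    """Multi-group comparison with a variance-equality gate.

    Levene's test (center = median) at ``gate_alpha`` decides the branch:
    equal variances -> one-way ANOVA across all groups; unequal variances ->
    pairwise two-sided Mann-Whitney tests of each group against the first
    (baseline) group, reported in ``pairwise`` as (label, U, p) with the
    smallest pairwise p echoed as the headline ``p_value`` (unadjusted).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("compare_multi needs >= 3 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} needs n >= 2, got {g.size}")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    gate_stat, gate_p = sps.levene(*groups, center="median")
    if gate_p >= gate_alpha:
        f, p = sps.f_oneway(*groups)
        return TestResult(comparison, "anova", float(f), float(p),
                          variance_gate_p=float(gate_p))
    baseline = groups[0]
    pairwise = []
    for lab, g in zip(labels[1:], groups[1:]):
        u, p = sps.mannwhitneyu(g, baseline, alternative="two-sided")
        pairwise.append((lab, float(u), float(p)))
    best = min(pairwise, key=lambda row: row[2])
    return TestResult(comparison, "mann_whitney", best[1], best[2],
                      variance_gate_p=float(gate_p), pairwise=tuple(pairwise))


def pearson_corr(x, y, regression: bool = False, pair: str = "x_vs_y") -> CorrelationResult:
    """Pearson correlation with a two-tailed p from the t transform.

    ``regression=True`` adds the least-squares slope and intercept of
    y on x.  Requires n >= 3 finite pairs and nonzero variance in both
    variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    slope = intercept = float("nan")
    if regression:
        fit = sps.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return CorrelationResult(pair=pair, n=int(x.size), r=float(r),
                             p_value=float(p), slope=slope, intercept=intercept)


def correlate_timecourses(wss_table: pd.DataFrame, measure_table: pd.DataFrame,
                          mode: str = "vs_wss", by=None,
                          days=None) -> pd.DataFrame:
    """Correlate per-day group means of a measure against time or WSS.

    Parameters
    ----------
    wss_table : DataFrame
        Per-day WSS summary with columns ``day`` and ``mean`` (as produced by
        :func:`avfstudy.hemodynamics.wss_timecourse`).
    measure_table : DataFrame
        Per-day summary of a measure with ``day`` and ``mean`` columns plus
        optional key columns (``marker`` / ``pair`` / ``compartment``).
    mode : {"vs_wss", "vs_time"}
        ``vs_time`` correlates measure means against the day number;
        ``vs_wss`` against the same-day WSS means.
    by : list of str, optional
        Key columns of ``measure_table``; one correlation per key combination.
    days : iterable, optional
        Restrict to these study days.

    Returns a DataFrame with one row per key: n (shared days), r, p, slope,
    intercept.
    """
    if mode not in ("vs_wss", "vs_time"):
        raise ValueError("mode must be 'vs_wss' or 'vs_time'")
    if by is None:
        by = [c for c in ("marker", "pair", "compartment") if c in measure_table.columns]
    wss = wss_table[["day", "mean"]].rename(columns={"mean": "wss_mean"})
    rows = []
    grouped = measure_table.groupby(by) if by else [((), measure_table)]
    for key, sub in grouped:
        merged = sub[["day", "mean"]].merge(wss, on="day", how="inner")
        if days is not None:
            merged = merged[merged["day"].isin(list(days))]
        if len(merged) < 3:
            raise ValueError(
                f"fewer than 3 shared days for key {key!r}; cannot correlate"
            )
        x = merged["day"].to_numpy(float) if mode == "vs_time" \
            else merged["wss_mean"].to_numpy(float)
        key_tuple = key if isinstance(key, tuple) else (key,)
        name = "/".join(str(k) for k in key_tuple) if by else "measure"
        res = pearson_corr(x, merged["mean"].to_numpy(float), regression=True,
                           pair=f"{name} {mode}")
        row = dict(zip(by, key_tuple))
        row.update(mode=mode, n=res.n, r=res.r, p_value=res.p_value,
                   slope=res.slope, intercept=res.intercept)
        rows.append(row)
    return pd.DataFrame(rows)


def holm_adjust(p_values):
    """Holm step-down adjustment (off by default everywhere; provided for
    sensitivity analyses)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def timecourse_summary(df: pd.DataFrame, value: str, by, baseline_day: int = -1,
                       day_col: str = "day") -> pd.DataFrame:
    """Group a long-format measurement table into a per-day time-course.

    For every combination of the ``by`` key columns: per-day n, mean and SE
    of ``value``, and the percent change of each day's group mean versus the
    baseline day's group mean.  Refuses tables whose baseline day is missing
    or where any group has fewer than 2 replicates (no variance estimate).
    """
    required = set(by) | {day_col, value}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    rows = []
    grouped = df.groupby(list(by)) if by else [((), df)]
    for key, sub in grouped:
        key_tuple = key if isinstance(key, tuple) else (key,)
        days = sorted(sub[day_col].unique())
        if baseline_day not in days:
            raise ValueError(
                f"baseline day {baseline_day} missing for {dict(zip(by, key_tuple))}"
            )
        per_day = {}
        for day in days:
            vals = sub.loc[sub[day_col] == day, value].to_numpy(float)
            if vals.size < 2:
                raise ValueError(
                    f"day {day} has n={vals.size} < 2 replicates for "
                    f"{dict(zip(by, key_tuple))}; refusing variance estimate"
                )
            per_day[day] = summarize(vals)
        base_mean = per_day[baseline_day].mean
        for day in days:
            s = per_day[day]
            row = dict(zip(by, key_tuple))
            # a percent change needs a positive baseline; report NaN otherwise
            pct = (100.0 * (s.mean - base_mean) / base_mean
                   if base_mean > 0 else float("nan"))
            row.update(day=day, n=s.n, mean=s.mean, se=s.se, pct_change=pct)
            rows.append(row)
    return pd.DataFrame(rows)
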
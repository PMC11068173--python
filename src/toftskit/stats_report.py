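"""Cohort statistics: summary grids, omnibus and post hoc tests.

The analysis plan mirrors common preclinical imaging practice: values
are reported as median (IQR); within-group change over days is tested
by one-way repeated-measures ANOVA (sphericity assumed); between-group
differences at each day use either ANOVA-family parametric comparisons
or, when normality fails (Shapiro–Wilk, α = 0.05 per group), the
Kruskal–Wallis omnibus test followed by pairwise Mann–Whitney post hoc
tests over the six group pairs with Bonferroni correction applied
within each metric × day family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "ComparisonResult",
    "validate_cohort",
    "summarize_table",
    "kruskal_wallis",
    "mann_whitney",
    "rm_anova",
    "pairwise_posthoc",
    "percent_change",
    "normality_ok",
    "analyze_cohort",
]

REQUIRED_COLUMNS = ("subject", "group", "day", "metric", "value")


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    day: int | None
    label: str  # pair "A vs B" or omnibus name
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: tuple
    defined: bool = True
    note: str = ""


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort table contract.

    One value per subject × day × metric; required columns present.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject", "day", "metric"])
    if dup.any():
        raise ValueError("cohort table has duplicate subject×day×metric rows")
    return table


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day median (Q1, Q3) grid for every metric.

    Quantiles use linear interpolation. Cells with no observations are
    kept in the grid as NaN (marked missing) rather than dropped.
    """
    validate_cohort(table)
    groups = list(pd.unique(table["group"]))
    days = sorted(pd.unique(table["day"]))
    metrics = list(pd.unique(table["metric"]))
    rows = []
    for metric in metrics:
        for day in days:
            for group in groups:
                sel = table[(table["metric"] == metric) & (table["day"] == day)
                            & (table["group"] == group)]["value"].to_numpy()
                if sel.size:
                    q1, med, q3 = np.quantile(sel, [0.25, 0.5, 0.75])
                else:
                    q1 = med = q3 = np.nan
                rows.append((metric, day, group, med, q1, q3, sel.size))
    return pd.DataFrame(
        rows, columns=["metric", "day", "group", "median", "q1", "q3", "n"]
    )


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal–Wallis H across groups, tie-corrected, chi² p (df = k−1).

    If every value is identical the statistic is undefined and the
    result is flagged rather than raising.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size < 2:
        return TestResult(np.nan, np.nan, (len(arrays) - 1,), defined=False,
                          note="all values identical; H undefined")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), (len(arrays) - 1,))


def mann_whitney(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``auto`` uses the exact null distribution (full enumeration) when
    n_a + n_b <= 12 with no ties, and the tie-corrected normal
    approximation otherwise; ``exact``/``asymptotic`` force a branch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if mode == "auto":
        method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    else:
        method = mode
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), (a.size, b.size),
                      note=method)


def rm_anova(values: np.ndarray, subjects=None) -> TestResult:
    """One-way repeated-measures ANOVA across conditions (days).

    ``values`` is (n_subjects, k_conditions) of complete cases;
    sphericity is assumed. F has (k−1, (k−1)(n−1)) degrees of freedom.
    Fewer than two complete subjects → flagged, no test. Identical
    values across conditions for every subject give F = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be (n_subjects, k_conditions)")
    complete = ~np.isnan(v).any(axis=1)
    n_excluded = int((~complete).sum())
    v = v[complete]
    n, k = v.shape
    if n < 2 or k < 2:
        return TestResult(np.nan, np.nan, (k - 1, (k - 1) * (n - 1)),
                          defined=False,
                          note=f"{n} complete subjects; need >= 2")
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "condition": np.tile(np.arange(k), n),
        "value": v.ravel(),
    })
    if np.allclose(v.var(axis=0).sum(), 0) or np.allclose(v, v[:, [0]]):
        # degenerate: no within-subject variation across conditions
        return TestResult(0.0, 1.0, (k - 1, (k - 1) * (n - 1)),
                          note=f"excluded={n_excluded}")
    res = AnovaRM(long, depvar="value", subject="subject",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return TestResult(float(row["F Value"]), float(row["Pr > F"]),
                      (int(row["Num DF"]), int(row["Den DF"])),
                      note=f"excluded={n_excluded}")


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p, capped at 1."""
    return min(1.0, p_raw * n_comparisons)


def pairwise_posthoc(
    table: pd.DataFrame,
    metric: str,
    day: int,
    correction: str = "bonferroni",
    policy: str = "if-significant",
    alpha: float = 0.05,
    mode: str = "auto",
) -> list[ComparisonResult]:
    """All pairwise group comparisons at one day for one metric.

    Runs the Kruskal–Wallis omnibus first; post hoc Mann–Whitney tests
    over every group pair are run either always (``policy='always'``)
    or only when the omnibus is significant (default). Adjusted p-values
    are Bonferroni-corrected within this metric × day family and capped
    at 1.
    """
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}; valid: 'bonferroni'")
    if policy not in ("always", "if-significant"):
        raise ValueError("policy must be 'always' or 'if-significant'")
    validate_cohort(table)
    sel = table[(table["metric"] == metric) & (table["day"] == day)]
    groups = list(pd.unique(sel["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = {g: sel[sel["group"] == g]["value"].to_numpy() for g in groups}
    omnibus = kruskal_wallis([data[g] for g in groups])
    results = [ComparisonResult(metric, day, "Kruskal-Wallis",
                                omnibus.statistic, omnibus.p_value,
                                omnibus.p_value, "kruskal-wallis")]
    run_posthoc = policy == "always" or (
        omnibus.defined and omnibus.p_value < alpha
    )
    if run_posthoc:
        pairs = list(combinations(groups, 2))
        for g1, g2 in pairs:
            mw = mann_whitney(data[g1], data[g2], mode=mode)
            results.append(ComparisonResult(
                metric, day, f"{g1} vs {g2}", mw.statistic, mw.p_value,
                bonferroni(mw.p_value, len(pairs)),
                f"mann-whitney ({mw.note}), bonferroni x{len(pairs)}",
            ))
    return results


def percent_change(baseline: float, followup: float) -> float:
    """Signed percent change 100·(follow-up − baseline)/baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero for percent change")
    return 100.0 * (followup - baseline) / baseline


def normality_ok(samples: list[np.ndarray], alpha: float = 0.05) -> bool:
    """Shapiro–Wilk normality gate: True iff no group rejects at alpha."""
    for s in samples:
        s = np.asarray(s, dtype=float)
        if s.size < 3 or np.unique(s).size < 2:
            return False
        if sps.shapiro(s).pvalue < alpha:
            return False
    return True


def analyze_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    force_branch: str | None = None,
) -> dict:
    """Full statistics report on a cohort table.

    For every metric: the summary grid, within-group repeated-measures
    ANOVA across days, and per-day between-group comparisons. The
    between-group branch is parametric only if every group passes the
    normality gate (override with ``force_branch='anova'|'kruskal'``);
    the report records which branch ran.
    """
    validate_cohort(table)
    if force_branch not in (None, "anova", "kruskal"):
        raise ValueError("force_branch must be None, 'anova' or 'kruskal'")
    summary = summarize_table(table)
    days = sorted(pd.unique(table["day"]))
    metrics = list(pd.unique(table["metric"]))
    groups = list(pd.unique(table["group"]))

    within = []
    for metric in metrics:
        for group in groups:
            sub = table[(table["metric"] == metric) & (table["group"] == group)]
            wide = sub.pivot(index="subject", columns="day", values="value")
            wide = wide.reindex(columns=days)
            r = rm_anova(wide.to_numpy())
            within.append({"metric": metric, "group": group,
                           "F": r.statistic, "p": r.p_value,
                           "df": r.df, "defined": r.defined, "note": r.note})

    between = []
    branches = {}
    for metric in metrics:
        for day in days:
            sel = table[(table["metric"] == metric) & (table["day"] == day)]
            samples = [sel[sel["group"] == g]["value"].to_numpy() for g in groups]
            if force_branch is not None:
                branch = force_branch
            else:
                branch = "anova" if normality_ok(samples, alpha) else "kruskal"
            branches[(metric, day)] = branch
            if branch == "anova":
                f, p = sps.f_oneway(*samples)
                between.append(ComparisonResult(metric, day, "one-way ANOVA",
                                                float(f), float(p), float(p),
                                                "anova"))
                if p < alpha:
                    pairs = list(combinations(groups, 2))
                    sel_data = {g: s for g, s in zip(groups, samples)}
                    for g1, g2 in pairs:
                        t, pr = sps.ttest_ind(sel_data[g1], sel_data[g2])
                        between.append(ComparisonResult(
                            metric, day, f"{g1} vs {g2}", float(t), float(pr),
                            bonferroni(float(pr), len(pairs)),
                            f"t-test, bonferroni x{len(pairs)}"))
            else:
                between.extend(pairwise_posthoc(table, metric, day, alpha=alpha))
    return {"summary": summary, "within_group": pd.DataFrame(within),
            "between_group": pd.DataFrame([vars(c) for c in between]),
            "branches": branches}
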
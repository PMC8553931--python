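"""Group-comparison statistics computable from printed summary data.

Implements the closed-form tests a demographics table reports: pooled
two-sample t from (mean, SD, n) rows, one-way ANOVA from summaries, Pearson
chi-square on count tables, the tie-corrected normal-approximation
Mann-Whitney U, and the two-tailed p of a Pearson r at given n. A report
builder reproduces the table from a raw clinical TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryRow",
    "TestResult",
    "ttest_from_summary",
    "anova_from_summary",
    "chi_square_table",
    "mann_whitney_ranked",
    "pearson_p_from_r",
    "moment_exact_sample",
    "table1_report",
]


@dataclass(frozen=True)
class SummaryRow:
    """A printed group summary: mean ± SD over n subjects."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: object                    # int, float or (df1, df2)
    p: float
    test_name: str


def ttest_from_summary(a: SummaryRow, b: SummaryRow,
                       welch: bool = False) -> TestResult:
    """Two-sample t-test from summary rows (pooled variance by default)."""
    d = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if d == 0:
            return TestResult(0.0, a.n + b.n - 2, 1.0, "t")
        raise ValueError("zero variance in both groups with unequal means")
    if welch:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        t = d / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
        t = d / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), "t (Welch)" if welch else "t")


def anova_from_summary(rows) -> TestResult:
    """One-way ANOVA F from (mean, SD, n) rows: F = MS_between / MS_within."""
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([r.n for r in rows], dtype=float)
    means = np.array([r.mean for r in rows])
    sds = np.array([r.sd for r in rows])
    N, k = ns.sum(), len(rows)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds ** 2).sum()
    df1, df2 = k - 1, int(N - k)
    if ssw == 0:
        if ssb == 0:
            return TestResult(0.0, (df1, df2), 1.0, "anova")
        raise ValueError("zero within-group variance with unequal means")
    F = (ssb / df1) / (ssw / df2)
    return TestResult(float(F), (df1, df2), float(stats.f.sf(F, df1, df2)), "anova")


def chi_square_table(counts) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return TestResult(float(chi2), int(dof), float(p), "chi2")


def mann_whitney_ranked(x, y) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    Z is signed so that a first sample with lower ranks gives Z < 0, and the
    two-tailed p comes from the standard normal (the SPSS-style asymptotic
    test, no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return TestResult(0.0, np.nan, 1.0, "mann-whitney")
    z = (u1 - mu) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return TestResult(float(z), np.nan, float(p), "mann-whitney")


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p of a Pearson r via t = r*sqrt(n-2)/sqrt(1-r^2), df=n-2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
    return float(2 * stats.t.sf(abs(t), n - 2))


def moment_exact_sample(mean: float, sd: float, n: int, rng=None) -> np.ndarray:
    """A sample of size n whose sample mean and SD (ddof=1) match exactly.

    An arbitrary draw is affinely adjusted to the requested moments, so
    summary-statistic formulas can be cross-checked against raw-data tests.
    """
    rng = np.random.default_rng(rng)
    x = rng.standard_normal(n)
    while np.std(x, ddof=1) == 0:
        x = rng.standard_normal(n)
    x = (x - x.mean()) / np.std(x, ddof=1)
    return mean + sd * x


# Variables of the demographics report and which test applies to each.
_TABLE1_PLAN = [
    ("age", "anova"), ("mmse", "anova"), ("fd", "anova"),
    ("illness_duration", "ttest"), ("hoehn_yahr", "mwu"),
    ("updrs3", "ttest"), ("ledd", "ttest"),
]


def table1_report(clinical: pd.DataFrame, groups=("FOG", "NFOG", "HC"),
                  fd_by_subject: pd.Series | None = None) -> pd.DataFrame:
    """Recompute the demographics/clinical comparison table from raw rows.

    Sex is compared by chi-square across all three groups; age, MMSE (and
    mean FD if provided) by one-way ANOVA; illness duration, UPDRS III and
    LEDD by pooled two-sample t between the two patient groups; Hoehn-Yahr
    by Mann-Whitney U. Returns one row per variable with group summaries,
    the statistic and its p-value.
    """
    df = clinical.copy()
    if fd_by_subject is not None:
        df["fd"] = df["subject_id"].map(fd_by_subject)
    rows = []
    counts = np.array([
        [(df[(df.group == g) & (df.sex == "M")]).shape[0] for g in groups],
        [(df[(df.group == g) & (df.sex == "F")]).shape[0] for g in groups],
    ])
    res = chi_square_table(counts)
    rows.append({"variable": "sex", "test": "chi2",
                 "statistic": res.statistic, "p": res.p})
    for var, kind in _TABLE1_PLAN:
        if var not in df.columns or df[var].dropna().empty:
            continue
        per_group = {g: df.loc[df.group == g, var].dropna().to_numpy()
                     for g in groups}
        if kind == "anova":
            srows = [SummaryRow(v.mean(), v.std(ddof=1), len(v))
                     for v in per_group.values() if len(v) >= 2]
            res = anova_from_summary(srows)
        elif kind == "ttest":
            a, b = per_group[groups[0]], per_group[groups[1]]
            res = ttest_from_summary(
                SummaryRow(a.mean(), a.std(ddof=1), len(a)),
                SummaryRow(b.mean(), b.std(ddof=1), len(b)))
        else:
            res = mann_whitney_ranked(per_group[groups[0]], per_group[groups[1]])
        summary = {
            f"{g}": (f"{v.mean():.3f} ± {v.std(ddof=1):.3f}" if len(v) else "NA")
            for g, v in per_group.items()}
        rows.append({"variable": var, "test": res.test_name,
                     "statistic": res.statistic, "p": res.p, **summary})
    return pd.DataFrame(rows)
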
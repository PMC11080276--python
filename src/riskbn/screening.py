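"""Univariate case-vs-control screening of candidate risk factors.

Each variable is compared between one case group and the control group with
the test matching its type: Pearson chi-square (no continuity correction)
for categorical variables, Welch's two-sample t test for approximately
symmetric continuous variables, and the normal-approximation Mann-Whitney
rank test (reported as Z) for the designated right-skewed labs.  Variables
with P below ``alpha`` (default 0.05) pass the gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import CATEGORICAL, GROUP_COLUMN, Codebook


@dataclass(frozen=True)
class TestResult:
    """One univariate test: statistic name, value, df (chi2 only), p."""

    statistic_name: str  # "chi2", "t" or "Z"
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")
        if self.statistic_name == "chi2" and self.statistic < 0:
            raise ValueError("chi-square statistic must be nonnegative")


def pearson_chi2(table) -> TestResult:
    """Pearson chi-square on an R x C contingency table (no Yates correction)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult("chi2", float(chi2), float(p), df=float(df))


def welch_t(a, b, *, pooled: bool = False) -> TestResult:
    """Two-independent-sample t test from raw samples or (mean, sd, n) summaries.

    Welch (unequal variances) by default; ``pooled=True`` gives the classic
    equal-variance test.  Summary input is a 3-tuple ``(mean, sd, n)``.
    """

    def _summ(x):
        if isinstance(x, tuple) and len(x) == 3:
            return float(x[0]), float(x[1]), int(x[2])
        arr = np.asarray(x, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)), arr.size

    m1, s1, n1 = _summ(a)
    m2, s2, n2 = _summ(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("negative sd")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            warnings.warn("both sds zero with equal means; t undefined, "
                          "returning 0", stacklevel=2)
            return TestResult("t", 0.0, 1.0)
        raise ValueError("zero variance with unequal means")
    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=pooled
    )
    return TestResult("t", float(res.statistic), float(res.pvalue))


def mann_whitney_z(a, b) -> TestResult:
    """Rank-sum test via the tie-corrected normal approximation.

    Returns the signed Z statistic ``(U - n1*n2/2) / sigma_U`` with U the
    Mann-Whitney statistic of the first sample, and the two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        warnings.warn("all values tied; Z undefined, returning 0",
                      stacklevel=2)
        return TestResult("Z", 0.0, 1.0)
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult("Z", float(z), float(min(p, 1.0)))


def screen_variables(
    cohort: pd.DataFrame,
    case_group: str,
    codebook: Codebook,
    alpha: float = 0.05,
    *,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Univariate screen of every variable, case group vs control.

    Returns a report with one row per tested variable: test name, statistic,
    df, p-value and the selection flag ``p < alpha``.  Variables in the
    codebook's exclusion list for this outcome (fasting glucose for the
    diabetic outcome) are omitted entirely.  ``adjust`` may be
    ``"bonferroni"`` or ``"fdr"`` (Benjamini-Hochberg); default is the
    unadjusted gate.
    """
    groups = set(cohort[GROUP_COLUMN].unique())
    if case_group not in groups:
        raise ValueError(f"case group {case_group!r} not present in cohort")
    if "control" not in groups:
        raise ValueError("cohort has no control group")
    excluded = set(codebook.excluded_for(case_group))
    sub = cohort[cohort[GROUP_COLUMN].isin(["control", case_group])]
    is_case = (sub[GROUP_COLUMN] == case_group).to_numpy()

    rows = []
    for var in cohort.columns:
        if var == GROUP_COLUMN or var in excluded:
            continue
        spec = codebook[var]
        x = sub[var].to_numpy()
        if spec.kind == CATEGORICAL:
            codes = sorted(np.unique(x))
            table = np.array(
                [
                    [np.sum((x == c) & ~is_case) for c in codes],
                    [np.sum((x == c) & is_case) for c in codes],
                ]
            )
            # drop empty state columns so margins stay positive
            table = table[:, table.sum(axis=0) > 0]
            res = pearson_chi2(table)
        elif spec.skewed:
            res = mann_whitney_z(x[~is_case], x[is_case])
        else:
            res = welch_t(x[~is_case], x[is_case])
        rows.append(
            {
                "variable": var,
                "test": res.statistic_name,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    report = pd.DataFrame(rows)
    p = report["p_value"].to_numpy()
    if adjust == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    elif adjust == "fdr":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty_like(p)
        p_adj[order] = np.minimum(ranked, 1.0)
    elif adjust is None:
        p_adj = p
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    report["selected"] = p_adj < alpha
    return report


def selected_variables(report: pd.DataFrame) -> list[str]:
    return report.loc[report["selected"], "variable"].tolist()
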
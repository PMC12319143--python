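"""Group-level inferential statistics.

Paired t-tests with Cohen's d for dependent samples (d = t / sqrt(n), i.e.
mean difference over the SD of the differences), 2x2 repeated-measures
ANOVA (Category x Trial-type) with partial eta squared, and Pearson
correlations.  For a 2x2 within design every ANOVA effect is equivalent to
a paired t-test on the corresponding difference contrast (F = t^2), which
serves as an internal cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import pingouin as pg


@dataclass
class TestReport:
    statistic: float          # t or F
    df: tuple                 # (df,) for t, (df_num, df_den) for F
    p: float
    effect_size: float        # Cohen's d or partial eta squared
    n: int
    flag: str = ""


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's d from a t statistic and sample size."""
    return t / np.sqrt(n)


def partial_eta_sq(F: float, df_num: int, df_den: int) -> float:
    """Partial eta squared from an F statistic and its degrees of freedom."""
    if F < 0 or df_num < 1 or df_den < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    return (F * df_num) / (F * df_num + df_den)


def paired_t(x, y) -> TestReport:
    """Two-sided dependent-samples t-test of x vs y (pairwise deletion)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return TestReport(0.0, (n - 1,), 1.0, 0.0, n)
        t = np.inf if diff.mean() > 0 else -np.inf
        return TestReport(t, (n - 1,), 0.0, np.sign(diff.mean()) * np.inf,
                          n, flag="zero_variance")
    t, p = sps.ttest_rel(x, y)
    return TestReport(float(t), (n - 1,), float(p),
                      cohens_d_from_t(float(t), n), n)


def pearson_r(x, y) -> TestReport:
    """Pearson correlation, two-sided p, df = n - 2 (pairwise deletion)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        return TestReport(np.nan, (n - 2,), np.nan, np.nan, n,
                          flag="zero_variance")
    r, p = sps.pearsonr(x, y)
    return TestReport(float(r), (n - 2,), float(p), float(r), n)


def rm_anova_2x2(cells: pd.DataFrame, dv: str = "value",
                 subject: str = "participant_id",
                 factors: tuple[str, str] = ("category", "trial_type"),
                 ) -> dict[str, TestReport]:
    """Two-way fully within-subject ANOVA on a long table of cell means.

    Participants with an incomplete 2x2 cell set are dropped (listwise).
    Returns reports keyed by each factor name and ``"interaction"``, each
    with partial eta squared attached.
    """
    a, b = factors
    counts = cells.groupby(subject)[dv].count()
    complete = counts[counts == 4].index
    data = cells[cells[subject].isin(complete)].copy()
    n = len(complete)
    if n < 3:
        raise ValueError("need at least 3 participants with complete cells")

    aov = pg.rm_anova(data=data, dv=dv, within=[a, b], subject=subject,
                      detailed=True)
    out: dict[str, TestReport] = {}
    for _, row in aov.iterrows():
        source = row["Source"]
        key = "interaction" if "*" in source else source
        F = float(row["F"])
        df1, df2 = int(row["ddof1"]), int(row["ddof2"])
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p = float(row[p_col])
        if not np.isfinite(F):
            # zero effect and zero error variance (all cells identical)
            F, p = 0.0, 1.0
        out[key] = TestReport(F, (df1, df2), p,
                              partial_eta_sq(F, df1, df2), n)
    return out


@dataclass
class ConditionComparison:
    """One Table-row of the condition analysis for a single variable."""
    variable: str
    mean_choc: float
    sd_choc: float
    mean_neutral: float
    sd_neutral: float
    t: TestReport
    r_choc: TestReport | None = None
    r_neutral: TestReport | None = None
    extras: dict = field(default_factory=dict)


def compare_conditions(wide: pd.DataFrame, intake: pd.Series | None,
                       variable: str) -> ConditionComparison:
    """Chocolate-vs-neutral comparison of per-participant means, plus raw
    correlations of each condition with intake.

    ``wide`` is indexed by participant with columns "chocolate"/"neutral";
    ``intake`` is aligned on the same index.
    """
    x = wide["chocolate"]
    y = wide["neutral"]
    rep = ConditionComparison(
        variable=variable,
        mean_choc=float(np.nanmean(x)), sd_choc=float(np.nanstd(x, ddof=1)),
        mean_neutral=float(np.nanmean(y)),
        sd_neutral=float(np.nanstd(y, ddof=1)),
        t=paired_t(x, y))
    if intake is not None:
        intake = intake.reindex(wide.index)
        rep.r_choc = pearson_r(x, intake)
        rep.r_neutral = pearson_r(y, intake)
    return rep
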
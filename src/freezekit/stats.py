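"""Statistical tests for window-based freezing data.

The analysis design is fully within-subject: every mouse contributes a
preCS and a CS freezing value for each of the six tone blocks of a
session, giving a balanced mouse x time (CS index) x period (preCS vs CS)
layout.  The period effect — whether tone presentation changes freezing —
and its interaction with time are assessed by a two-way repeated-measures
ANOVA; per-mouse mean CS-induced differences are tested against zero with
a one-sample t-test (after Shapiro-Wilk normality screening), groups are
compared with a two-sample t-test, and the external-inhibition relation
is quantified by a Pearson correlation.

All tests are two-sided; p-values are reported at full precision and star
thresholds (0.05 / 0.01 / 0.001) are presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "TestResult",
    "two_way_rm_anova",
    "one_sample_t",
    "two_sample_t",
    "shapiro_wilk",
    "pearson",
    "window_table_to_long",
    "stars",
]


@dataclass(frozen=True)
class AnovaTerm:
    F: float
    p: float
    df1: int
    df2: int
    ss: float


@dataclass(frozen=True)
class RmAnovaResult:
    """Two-way repeated-measures ANOVA: time, period and their interaction."""

    time: AnovaTerm
    period: AnovaTerm
    interaction: AnovaTerm
    n_subjects: int
    #: Greenhouse-Geisser corrected p-values (None when not requested).
    p_gg: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("time", "period", "interaction"):
            t: AnovaTerm = getattr(self, name)
            rows.append(
                {
                    "term": name,
                    "statistic": t.F,
                    "df1": t.df1,
                    "df2": t.df2,
                    "SS": t.ss,
                    "p": t.p,
                    "stars": stars(t.p),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float
    test: str

    def to_row(self) -> dict:
        return {
            "term": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "stars": stars(self.p),
        }


def stars(p: float) -> str:
    """Significance stars at p <= 0.05 (*), 0.01 (**), 0.001 (***)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def window_table_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a window table to long format for the RM ANOVA.

    Input columns: mouse_id, cs_index, pre_cs_pct, cs_pct_corrected.
    Output columns: mouse_id, time (CS index), period ('preCS'|'CS'), pct.
    """
    pre = table[["mouse_id", "cs_index", "pre_cs_pct"]].rename(
        columns={"pre_cs_pct": "pct"}
    )
    pre["period"] = "preCS"
    cs = table[["mouse_id", "cs_index", "cs_pct_corrected"]].rename(
        columns={"cs_pct_corrected": "pct"}
    )
    cs["period"] = "CS"
    long = pd.concat([pre, cs], ignore_index=True)
    return long.rename(columns={"cs_index": "time"})


def two_way_rm_anova(
    long: pd.DataFrame,
    dv: str = "pct",
    within: tuple[str, str] = ("time", "period"),
    subject: str = "mouse_id",
    *,
    gg_correction: bool = False,
) -> RmAnovaResult:
    """Univariate two-way repeated-measures ANOVA on a balanced layout.

    Each within-subject factor is tested against its own subject-by-factor
    error term.  No sphericity correction is applied by default;
    Greenhouse-Geisser corrected p-values are attached when
    ``gg_correction`` is set.

    Raises ``ValueError`` on an unbalanced/incomplete layout.
    """
    f1, f2 = within
    counts = long.groupby([subject, f1, f2], observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("layout must contain exactly one value per cell")
    n_sub = long[subject].nunique()
    n1 = long[f1].nunique()
    n2 = long[f2].nunique()
    if len(long) != n_sub * n1 * n2:
        raise ValueError("layout is unbalanced: missing factor combinations")

    aov = pg.rm_anova(
        data=long, dv=dv, within=[f1, f2], subject=subject, detailed=True
    )
    aov = aov.set_index("Source")

    def term(src: str) -> AnovaTerm:
        row = aov.loc[src]
        return AnovaTerm(
            F=float(row["F"]),
            p=float(row["p_unc"]),
            df1=int(row["ddof1"]),
            df2=int(row["ddof2"]),
            ss=float(row["SS"]),
        )

    inter_key = f"{f1} * {f2}"
    p_gg = None
    if gg_correction and "p_GG_corr" in aov.columns:
        p_gg = {
            "time": float(aov.loc[f1, "p_GG_corr"]),
            "period": float(aov.loc[f2, "p_GG_corr"]),
            "interaction": float(aov.loc[inter_key, "p_GG_corr"]),
        }
    return RmAnovaResult(
        time=term(f1),
        period=term(f2),
        interaction=term(inter_key),
        n_subjects=n_sub,
        p_gg=p_gg,
    )


def _check_sample(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"{name} needs at least 3 values")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


def one_sample_t(values, mu: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu``."""
    values = _check_sample(values, "one-sample t")
    if np.ptp(values) == 0:
        raise ValueError("one-sample t is undefined for zero-variance data")
    res = sps.ttest_1samp(values, popmean=mu)
    return TestResult(float(res.statistic), float(res.pvalue), values.size - 1,
                      "one-sample t")


def two_sample_t(a, b) -> TestResult:
    """Two-sided unpaired two-sample t-test (pooled variance)."""
    a = _check_sample(a, "sample a")
    b = _check_sample(b, "sample b")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("two-sample t is undefined for zero-variance data")
    res = sps.ttest_ind(a, b)
    return TestResult(float(res.statistic), float(res.pvalue),
                      a.size + b.size - 2, "two-sample t")


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test."""
    values = _check_sample(values, "Shapiro-Wilk")
    res = sps.shapiro(values)
    return TestResult(float(res.statistic), float(res.pvalue), values.size,
                      "Shapiro-Wilk")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
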
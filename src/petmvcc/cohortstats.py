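"""Cohort demographic comparisons: pooled two-sample t and Fisher's exact.

Continuous variables are compared with the pooled-variance (Student)
two-sample t-test — computable from printed group summaries (n, mean,
sample SD) with df = n1 + n2 - 2. Categorical variables are compared
with Fisher's exact test on a 2x2 table, two-sided by the
point-probability convention (summing hypergeometric probabilities of
all same-margin tables no more likely than the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ContingencyTable2x2",
    "TestResult",
    "two_sample_t",
    "fisher_exact",
    "compare_cohorts",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=np.float64)
        return cls(n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("counts must be nonnegative")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class TestResult:
    statistic: float  # t statistic, or odds ratio for Fisher
    p_two_sided: float
    df: int | None = None
    test: str = ""


def two_sample_t(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Pooled-variance Student t-test from group summaries."""
    pooled_var = (
        (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    ) / (g1.n + g2.n - 2)
    if pooled_var == 0 and g1.mean == g2.mean:
        raise ValueError("t statistic undefined: both groups are constant and equal")
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return TestResult(
        statistic=float(t), p_two_sided=float(p), df=g1.n + g2.n - 2, test="t"
    )


def fisher_exact(tbl: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test; statistic is the sample odds ratio.

    The odds ratio is a*d / (b*c), infinite when b*c = 0 with a*d > 0 and
    reported as nan for 0/0.
    """
    odds, p = stats.fisher_exact(tbl.array, alternative="two-sided")
    return TestResult(statistic=float(odds), p_two_sided=float(p), test="fisher")


def compare_cohorts(
    sheet: pd.DataFrame,
    variable: str,
    kind: str,
    group_col: str = "cohort",
    groups: tuple = None,
    positive_value=None,
) -> TestResult:
    """Dispatch a Table-style group comparison on a participant sheet.

    kind 'continuous' pools raw values into group summaries and runs the
    t-test; kind 'categorical' counts ``positive_value`` (default: truthy)
    per group into a 2x2 table and runs Fisher's exact test.
    """
    if groups is None:
        groups = tuple(pd.unique(sheet[group_col]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    sub1 = sheet[sheet[group_col] == groups[0]][variable]
    sub2 = sheet[sheet[group_col] == groups[1]][variable]
    if len(sub1) < 2 or len(sub2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind == "continuous":
        return two_sample_t(
            GroupSummary.from_values(sub1), GroupSummary.from_values(sub2)
        )
    if kind == "categorical":
        def pos(series):
            if positive_value is None:
                return int(series.astype(bool).sum())
            return int((series == positive_value).sum())

        a, c = pos(sub1), pos(sub2)
        tbl = ContingencyTable2x2(a=a, b=len(sub1) - a, c=c, d=len(sub2) - c)
        return fisher_exact(tbl)
    raise ValueError(f"unknown variable kind {kind!r}")
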
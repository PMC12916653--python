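"""Cohort demographic comparisons: Welch t-tests and Fisher exact tests.

Case/control cohorts are routinely compared on demographics (age, BMI,
parity, blood pressure, gestational diabetes, visit timing) before any
immunological modeling.  Continuous variables are compared with an unpaired
unequal-variance (Welch) t-test computed either from raw vectors or from
printed summary statistics (mean, SD, n); binary variables with a two-sided
Fisher exact test on the 2x2 count table.

The module also ships the printed summary statistics of the three study
cohorts (antepartum AP, postpartum PP, midlife ML) so the comparison table
can be rebuilt from summaries alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "CountTable2x2",
    "welch_t_from_summary",
    "fisher_exact_2x2",
    "build_table2",
    "summarize_arm",
    "REFERENCE_COHORT_SUMMARIES",
    "REFERENCE_COHORT_COUNTS",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one arm for a continuous variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2 for a variance-based test, got {self.n}")


@dataclass(frozen=True)
class CountTable2x2:
    """Counts (cases with / without, controls with / without) for a binary trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all 2x2 entries must be nonnegative")
        if (self.a + self.b) == 0 or (self.c + self.d) == 0:
            raise ValueError("both row margins must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Welch (unequal-variance) two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom and a
    two-sided p-value.  Degenerate inputs (both SDs zero) follow the
    convention p=1 for equal means and p=0 for unequal means.
    """
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        return float("inf"), float(g1.n + g2.n - 2), 0.0
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(t), float(df), float(p)


def fisher_exact_2x2(table: CountTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums the hypergeometric point probabilities of all tables with the
    observed margins that are no more probable than the observed table.
    """
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def summarize_arm(values: pd.Series) -> GroupSummary:
    """Mean/SD/n summary of a raw vector, excluding missing values."""
    v = pd.to_numeric(values, errors="coerce").dropna()
    return GroupSummary(float(v.mean()), float(v.std(ddof=1)), int(v.size))


# Printed per-arm summaries of the three study cohorts.  Continuous rows are
# (mean, sd, n); the reduced n on midlife case rows reflects one case with
# unknown information.
REFERENCE_COHORT_SUMMARIES: dict[str, dict[str, dict[str, tuple[float, float, int]]]] = {
    "AP": {
        "age": {"case": (33.86, 5.18, 28), "control": (32.95, 4.45, 38)},
        "parity": {"case": (0.79, 1.17, 28), "control": (0.42, 0.55, 38)},
        "bmi": {"case": (32.54, 6.94, 28), "control": (26.50, 3.56, 38)},
        "visit_timing": {"case": (33.32, 3.40, 28), "control": (33.50, 3.52, 38)},
        "systolic": {"case": (129.48, 14.75, 28), "control": (103.01, 15.86, 38)},
        "diastolic": {"case": (78.37, 8.39, 28), "control": (64.22, 6.97, 38)},
    },
    "PP": {
        "age": {"case": (34.10, 4.38, 42), "control": (33.51, 3.47, 37)},
        "parity": {"case": (1.67, 1.07, 42), "control": (1.38, 0.55, 37)},
        "bmi": {"case": (28.46, 6.54, 42), "control": (24.65, 3.47, 37)},
        "visit_timing": {"case": (16.81, 12.30, 42), "control": (9.61, 5.65, 37)},
        "systolic": {"case": (114.52, 9.46, 42), "control": (105.69, 8.01, 37)},
        "diastolic": {"case": (73.01, 7.42, 42), "control": (67.86, 6.16, 37)},
    },
    "ML": {
        "age": {"case": (40.20, 6.35, 70), "control": (40.89, 5.27, 74)},
        "parity": {"case": (2.07, 1.20, 69), "control": (1.97, 0.86, 74)},
        "bmi": {"case": (26.50, 4.98, 69), "control": (24.17, 4.90, 74)},
        "visit_timing": {"case": (5.87, 3.44, 70), "control": (5.87, 3.83, 74)},
        "systolic": {"case": (118.41, 10.76, 69), "control": (111.43, 11.30, 74)},
        "diastolic": {"case": (75.14, 8.52, 69), "control": (70.11, 9.12, 74)},
    },
}

# Binary traits as (cases with, cases total, controls with, controls total).
REFERENCE_COHORT_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "AP": {"gestational_diabetes": (6, 28, 0, 38)},
    "PP": {"gestational_diabetes": (8, 42, 0, 37)},
    "ML": {"gestational_diabetes": (6, 70, 0, 74)},
}

#: Variables treated as binary in the comparison table.
BINARY_VARIABLES = ("gestational_diabetes",)


def _compare_continuous(case: pd.Series, control: pd.Series) -> dict:
    g1, g2 = summarize_arm(case), summarize_arm(control)
    t, df, p = welch_t_from_summary(g1, g2)
    return {
        "test": "welch_t",
        "case_mean": g1.mean, "case_sd": g1.sd, "case_n": g1.n,
        "control_mean": g2.mean, "control_sd": g2.sd, "control_n": g2.n,
        "statistic": t, "p_value": p,
    }


def _compare_binary(case: pd.Series, control: pd.Series) -> dict:
    c = pd.to_numeric(case, errors="coerce").dropna().astype(int)
    k = pd.to_numeric(control, errors="coerce").dropna().astype(int)
    tab = CountTable2x2(int(c.sum()), int(c.size - c.sum()),
                        int(k.sum()), int(k.size - k.sum()))
    if tab.a == 0 and tab.c == 0:
        p = 1.0
    else:
        p = fisher_exact_2x2(tab)
    return {
        "test": "fisher_exact",
        "case_mean": 100.0 * tab.a / (tab.a + tab.b), "case_sd": np.nan,
        "case_n": tab.a + tab.b,
        "control_mean": 100.0 * tab.c / (tab.c + tab.d), "control_sd": np.nan,
        "control_n": tab.c + tab.d,
        "statistic": np.nan, "p_value": p,
    }


def build_table2(
    metadata: pd.DataFrame,
    variables: list[str] | None = None,
    cohort_col: str = "cohort",
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """Per-variable, per-cohort case/control comparison from raw metadata.

    Continuous variables get a Welch t-test, binary variables a two-sided
    Fisher exact test.  Missing values are excluded per variable and the
    effective n is reported.  Returns one row per (cohort, variable).
    """
    if variables is None:
        skip = {cohort_col, outcome_col, "sample_id"}
        variables = [c for c in metadata.columns if c not in skip]
    rows = []
    for cohort, sub in metadata.groupby(cohort_col, sort=False):
        case = sub[sub[outcome_col] == 1]
        control = sub[sub[outcome_col] == 0]
        if case.empty or control.empty:
            raise ValueError(f"cohort {cohort!r} lacks one of the two arms")
        for var in variables:
            if var not in sub.columns:
                continue
            if var in BINARY_VARIABLES or set(sub[var].dropna().unique()) <= {0, 1}:
                rec = _compare_binary(case[var], control[var])
            else:
                rec = _compare_continuous(case[var], control[var])
            rows.append({"cohort": cohort, "variable": var, **rec})
    return pd.DataFrame(rows)


def reference_table2() -> pd.DataFrame:
    """Comparison table rebuilt from the shipped printed summaries."""
    rows = []
    for cohort, variables in REFERENCE_COHORT_SUMMARIES.items():
        for var, arms in variables.items():
            g1 = GroupSummary(*arms["case"])
            g2 = GroupSummary(*arms["control"])
            t, df, p = welch_t_from_summary(g1, g2)
            rows.append({
                "cohort": cohort, "variable": var, "test": "welch_t",
                "case_mean": g1.mean, "case_sd": g1.sd, "case_n": g1.n,
                "control_mean": g2.mean, "control_sd": g2.sd, "control_n": g2.n,
                "statistic": t, "p_value": p,
            })
    for cohort, variables in REFERENCE_COHORT_COUNTS.items():
        for var, (a, n1, c, n0) in variables.items():
            tab = CountTable2x2(a, n1 - a, c, n0 - c)
            rows.append({
                "cohort": cohort, "variable": var, "test": "fisher_exact",
                "case_mean": 100.0 * a / n1, "case_sd": np.nan, "case_n": n1,
                "control_mean": 100.0 * c / n0, "control_sd": np.nan, "control_n": n0,
                "statistic": np.nan, "p_value": fisher_exact_2x2(tab),
            })
    return pd.DataFrame(rows)
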
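"""Shared inferential machinery for the stress-response pipeline.

Thin, explicitly-typed wrappers around scipy / statsmodels / pingouin that fix
the conventions used throughout the analysis: pooled-variance Student t tests
(Welch behind a flag), one-way ANOVA with Tukey-Kramer post hoc, a mixed-design
(between x within) repeated-measures ANOVA, Pearson correlation with the
t-transform p-value, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "two_sample_t",
    "oneway_anova",
    "tukey_kramer",
    "rm_anova_two_way",
    "pearson_with_p",
    "bh_fdr",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is a scalar for t tests and a (numerator, denominator) pair for F
    tests. ``direction`` is the sign of the effect (first argument minus
    second, or the sign of a correlation), 0 for omnibus tests.
    """

    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    direction: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def _as_clean_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be non-empty and finite")
    return arr


def two_sample_t(a, b, *, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test; pooled variance by default.

    The pooled (Student) form with df = n_a + n_b - 2 is the convention used
    for all group contrasts; Welch's unequal-variance form is available via
    ``welch=True``.
    """
    a = _as_clean_1d(a, "a")
    b = _as_clean_1d(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    if not np.isfinite(t):
        raise ValueError("degenerate samples: zero pooled variance")
    return TestResult(
        name="welch_t" if welch else "student_t",
        statistic=t,
        df=float(res.df),
        p=float(res.pvalue),
        direction=int(np.sign(t)),
    )


def oneway_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA across ``groups`` (list of 1-D samples)."""
    samples = [_as_clean_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2 or any(g.size < 2 for g in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(g) == 0 for g in samples):
        raise ValueError("degenerate input: zero within-group variance everywhere")
    f, p = sps.f_oneway(*samples)
    k = len(samples)
    n = sum(g.size for g in samples)
    return TestResult(name="oneway_anova", statistic=float(f), df=(k - 1, n - k), p=float(p))


def tukey_kramer(groups) -> np.ndarray:
    """Tukey-Kramer all-pairs p-values (studentized range, unequal n allowed).

    Returns a symmetric k x k matrix with NaN on the diagonal.
    """
    samples = [_as_clean_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2 or any(g.size < 2 for g in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = sps.tukey_hsd(*samples)
    p = np.asarray(res.pvalue, dtype=float).copy()
    np.fill_diagonal(p, np.nan)
    return p


def rm_anova_two_way(response: pd.DataFrame, group) -> dict[str, TestResult]:
    """Mixed-design ANOVA: between-subject group, within-subject time.

    Parameters
    ----------
    response
        Wide table, one row per subject, one column per within-subject level
        (e.g. sampling times); index identifies subjects.
    group
        Between-subject label per row of ``response``.

    Returns the three effects (``group``, ``time``, ``group x time``) with the
    standard univariate df partitioning, assuming sphericity (uncorrected df).
    """
    import pingouin as pg

    response = pd.DataFrame(response)
    group = np.asarray(group)
    if group.shape[0] != response.shape[0]:
        raise ValueError("one group label per subject required")
    if response.isna().any().any():
        raise ValueError("missing cells: every subject needs every time point")
    long = response.copy()
    long["_subject"] = np.arange(len(long))
    long["_group"] = group
    long = long.melt(
        id_vars=["_subject", "_group"], var_name="_time", value_name="_y"
    )
    aov = pg.mixed_anova(
        data=long, dv="_y", within="_time", subject="_subject",
        between="_group", correction=False,
    ).set_index("Source")

    p_col = "p-unc" if "p-unc" in aov.columns else "p_unc"

    def _row(src: str, label: str) -> TestResult:
        r = aov.loc[src]
        return TestResult(
            name=f"rm_anova[{label}]",
            statistic=float(r["F"]),
            df=(float(r["DF1"]), float(r["DF2"])),
            p=float(r[p_col]),
        )

    return {
        "group": _row("_group", "group"),
        "time": _row("_time", "time"),
        "group x time": _row("Interaction", "group x time"),
    }


def pearson_with_p(x, y) -> TestResult:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = _as_clean_1d(x, "x")
    y = _as_clean_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        name="pearson",
        statistic=float(r),
        df=float(x.size - 2),
        p=float(p),
        direction=int(np.sign(r)),
    )


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected, q)``: the boolean rejection mask at level ``alpha``
    and the BH-adjusted q-values (monotone, capped at 1), both in input order.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, q
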
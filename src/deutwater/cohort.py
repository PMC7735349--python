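"""Cohort-level descriptive and inferential statistics.

Operates on a long-format table of per-subject-period measurements
(columns: subject_id, sex, period order plus measurement variables).
Summaries follow the two-stage convention common in small longitudinal
cohorts: average within subject first, then summarize subject means within
groups with mean +/- SD (n-1 denominator, n = subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "CohortSummary",
    "subject_means",
    "group_summary",
    "normalize_to_subject_mean",
    "paired_first_last",
    "correlations",
    "turnover_mass_slope",
    "covariate_check_anova",
]


@dataclass(frozen=True)
class CohortSummary:
    group: str
    variable: str
    mean: float
    sd: float  # ddof=1 over subject means; NaN when n == 1
    n: int  # number of subjects


def subject_means(
    df: pd.DataFrame,
    variables: list[str] | None = None,
    *,
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Arithmetic mean of each variable over each subject's periods.

    Non-numeric grouping columns such as sex are carried through when they
    are constant within subject.
    """
    if variables is None:
        variables = [
            c
            for c in df.columns
            if c != subject_col and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = df.groupby(subject_col, sort=True)[variables].mean()
    for c in df.columns:
        if c in variables or c == subject_col:
            continue
        per = df.groupby(subject_col, sort=True)[c].agg(
            lambda s: s.iloc[0] if s.nunique(dropna=False) == 1 else np.nan
        )
        out[c] = per
    return out.reset_index()


def group_summary(
    df: pd.DataFrame,
    variable: str,
    *,
    group_col: str = "sex",
    subject_col: str = "subject_id",
) -> list[CohortSummary]:
    """Mean and SD of subject means within each group."""
    means = subject_means(df, [variable], subject_col=subject_col)
    out = []
    for g, sub in means.groupby(group_col, sort=True):
        vals = sub[variable].to_numpy(dtype=float)
        out.append(
            CohortSummary(
                group=str(g),
                variable=variable,
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                n=len(vals),
            )
        )
    return out


def normalize_to_subject_mean(
    df: pd.DataFrame,
    variables: list[str],
    *,
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Divide each measurement by the subject's study-long mean.

    Normalized values have subject-wise mean 1, putting subjects of very
    different size on a common relative scale for pooled trend plots.
    """
    out = df.copy()
    for v in variables:
        out[v] = df[v] / df.groupby(subject_col)[v].transform("mean")
    return out


def paired_first_last(
    df: pd.DataFrame,
    variable: str,
    *,
    subject_col: str = "subject_id",
    order_col: str = "period_order",
) -> tuple[float, int, float]:
    """Paired t-test of each subject's last minus first measurement.

    First/last are taken in ``order_col`` order among that subject's
    available (QC-passing) periods.  Returns (t, df, two-sided p).
    Zero variance in the differences with a non-zero mean is degenerate
    (|t| infinite); it raises ``ValueError`` rather than reporting a
    fabricated p-value.  All-zero differences return (0.0, n-1, 1.0).
    """
    firsts, lasts = [], []
    for _, sub in df.sort_values(order_col).groupby(subject_col):
        vals = sub[variable].dropna()
        if len(vals) >= 2:
            firsts.append(float(vals.iloc[0]))
            lasts.append(float(vals.iloc[-1]))
    n = len(firsts)
    if n < 2:
        raise ValueError("need >= 2 subjects with both first and last values")
    diff = np.asarray(lasts) - np.asarray(firsts)
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, n - 1, 1.0
        raise ValueError(
            "differences have zero variance but non-zero mean; paired t is undefined"
        )
    t, p = stats.ttest_rel(lasts, firsts)
    return float(t), n - 1, float(p)


def correlations(
    df: pd.DataFrame,
    x: str,
    y: str,
    scope: str = "pooled",
    *,
    subject_col: str = "subject_id",
) -> dict[str, tuple[float, float, int, float]]:
    """Pearson correlations, pooled or per subject.

    Returns a mapping scope-key -> (r, t, df, p) with t = r*sqrt(df/(1-r^2))
    and df = n-2.  Key is ``"pooled"`` or the subject id.
    """
    def _one(sub: pd.DataFrame) -> tuple[float, float, int, float]:
        xs = sub[x].to_numpy(dtype=float)
        ys = sub[y].to_numpy(dtype=float)
        if len(xs) < 3:
            raise ValueError(f"need >= 3 paired observations, have {len(xs)}")
        r, p = stats.pearsonr(xs, ys)
        dof = len(xs) - 2
        t = r * np.sqrt(dof / (1.0 - r * r)) if abs(r) < 1 else np.inf * np.sign(r)
        return float(r), float(t), dof, float(p)

    if scope == "pooled":
        return {"pooled": _one(df)}
    if scope == "within-subject":
        return {str(sid): _one(sub) for sid, sub in df.groupby(subject_col)}
    raise ValueError(f"scope must be 'pooled' or 'within-subject', got {scope!r}")


def turnover_mass_slope(
    df: pd.DataFrame,
    *,
    turnover_col: str = "water_turnover",
    mass_col: str = "body_mass",
    subject_col: str = "subject_id",
) -> float:
    """OLS slope of subject-mean turnover on subject-mean mass, per 100 kg.

    Returns litres per day gained per 100 kg of body mass across subjects.
    """
    means = subject_means(df, [turnover_col, mass_col], subject_col=subject_col)
    if len(means) < 2:
        raise ValueError("need >= 2 subjects")
    x = means[mass_col].to_numpy(dtype=float)
    y = means[turnover_col].to_numpy(dtype=float)
    slope = stats.linregress(x, y).slope
    return float(slope * 100.0)


def covariate_check_anova(
    df: pd.DataFrame,
    value_col: str,
    *,
    factor_a: str = "time_of_day",
    factor_b: str = "subject_id",
    typ: int = 2,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction, as a QC check.

    Tests whether ``value_col`` depends on ``factor_a`` (e.g. dosing time
    of day), ``factor_b`` (identity) and their interaction.  Returns the
    statsmodels ANOVA table (sum_sq, df, F, PR(>F)).
    """
    d = df.rename(columns={value_col: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    table.index = [
        str(i).replace("_a", factor_a).replace("_b", factor_b) for i in table.index
    ]
    return table
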
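"""Group-comparison and correlation statistics for wheeze-index cohorts.

Two-group comparisons use the unpaired t-test (Welch by default, since
the groups' variances plainly differ; the pooled-variance Student
variant is available). Index-vs-covariate associations use Pearson's
product-moment correlation. :func:`summarize_cohort` renders the two
standard reports: a per-group characteristics table with group-
comparison p-values, and a matrix of correlation p-values of each
wheeze index against each covariate. No multiple-testing correction is
applied.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import COVARIATE_COLUMNS, INDEX_COLUMNS

Summary = tuple[int, float, float]  # (n, mean, sd)


def _to_summary(x) -> Summary:
    if isinstance(x, tuple) and len(x) == 3:
        n, mean, sd = x
        if n < 2:
            raise ValueError("group size must be >= 2")
        if sd < 0:
            raise ValueError("sd must be >= 0")
        return int(n), float(mean), float(sd)
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("group size must be >= 2")
    return int(arr.size), float(arr.mean()), float(arr.std(ddof=1))


def unpaired_t(x, y, variant: str = "welch") -> tuple[float, float, float]:
    """Unpaired two-sample t-test from raw samples or (n, mean, sd)
    summaries.

    Returns ``(t, df, p_two_sided)``. ``variant='welch'`` (default) uses
    unequal variances with Welch-Satterthwaite degrees of freedom;
    ``'student'`` pools the variance.
    """
    n1, m1, s1 = _to_summary(x)
    n2, m2, s2 = _to_summary(y)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "welch":
        v1, v2 = s1 * s1 / n1, s2 * s2 / n2
        t = (m1 - m2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    elif variant == "student":
        sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
        t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value from
    the t transform on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(
    cohort: pd.DataFrame,
    group_col: str = "group",
    index_cols: Sequence[str] | None = None,
    covariate_cols: Sequence[str] | None = None,
    variant: str = "welch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary table and index-vs-covariate correlation table.

    Returns ``(group_table, correlation_table)``:

    * ``group_table`` — one row per variable with each group's
      ``mean``/``sd``/``n`` and the two-group t-test (t, df, p). With
      degenerate input (zero variance in both groups) the p-value is NaN
      and the row is flagged in the ``note`` column.
    * ``correlation_table`` — one row per (wheeze index, covariate) pair
      with Pearson r and p.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if group_col not in cohort.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = sorted(cohort[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    if index_cols is None:
        index_cols = [c for c in INDEX_COLUMNS if c in cohort.columns]
    if covariate_cols is None:
        covariate_cols = [c for c in COVARIATE_COLUMNS if c in cohort.columns]

    g0 = cohort[cohort[group_col] == groups[0]]
    g1 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for col in list(index_cols) + list(covariate_cols):
        a = g0[col].dropna().to_numpy(dtype=float)
        b = g1[col].dropna().to_numpy(dtype=float)
        row = {
            "variable": col,
            f"{groups[0]}_n": a.size,
            f"{groups[0]}_mean": a.mean() if a.size else math.nan,
            f"{groups[0]}_sd": a.std(ddof=1) if a.size > 1 else math.nan,
            f"{groups[1]}_n": b.size,
            f"{groups[1]}_mean": b.mean() if b.size else math.nan,
            f"{groups[1]}_sd": b.std(ddof=1) if b.size > 1 else math.nan,
        }
        try:
            t, df, p = unpaired_t(a, b, variant=variant)
            row.update(t=t, df=df, p=p, note="")
        except ValueError as e:
            row.update(t=math.nan, df=math.nan, p=math.nan, note=str(e))
        rows.append(row)
    group_table = pd.DataFrame(rows)

    corr_rows = []
    for ix in index_cols:
        for cov in covariate_cols:
            sub = cohort[[ix, cov]].dropna()
            try:
                r, p = pearson_r(sub[ix], sub[cov])
            except ValueError:
                r, p = math.nan, math.nan
            corr_rows.append({"index": ix, "covariate": cov, "r": r, "p": p})
    corr_table = pd.DataFrame(corr_rows, columns=["index", "covariate", "r", "p"])
    return group_table, corr_table
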
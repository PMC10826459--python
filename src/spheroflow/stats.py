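"""Condition summaries and Welch t-test comparisons of endpoint readouts.

The comparisons follow the study's reporting style: unequal-variance
(Welch) two-sample t-tests, two-sided p values, and star labels at the
strict thresholds p < 0.001 (***), p < 0.01 (**), p < 0.05 (*). No
multiple-testing correction is applied; both conventions are recorded in
the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "GroupComparison",
    "welch_ttest",
    "significance_label",
    "summarize_conditions",
]


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    stars: str


def welch_ttest(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sample t-test with unequal variances (Welch–Satterthwaite df).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b); two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate: both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=a.size,
        n_b=b.size,
        t=float(t),
        df=float(df),
        p=float(p),
        stars=significance_label(p),
    )


def significance_label(p: float) -> str:
    """Star label at strict thresholds: <0.001 ***, <0.01 **, <0.05 *, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_conditions(
    table: pd.DataFrame,
    value_col: str = "value",
    condition_col: str = "condition",
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition mean ± SD plus pairwise Welch comparisons.

    Returns (summary, comparisons). Each comparison row reports the Welch
    statistics and the percentage by which the second condition's mean is
    lower than the first's: 100 * (mean_a - mean_b) / mean_a.
    ``pairs=None`` compares all condition pairs (when each has n >= 2).
    """
    if condition_col not in table or value_col not in table:
        raise ValueError(f"table must have columns {condition_col!r} and {value_col!r}")
    groups = {
        str(k): np.asarray(v, dtype=float)
        for k, v in table.groupby(condition_col)[value_col]
    }
    if not groups:
        raise ValueError("no conditions in table")
    summary = pd.DataFrame(
        {
            "condition": list(groups),
            "n": [g.size for g in groups.values()],
            "mean": [g.mean() for g in groups.values()],
            "sd": [g.std(ddof=1) if g.size > 1 else np.nan for g in groups.values()],
        }
    )
    if pairs is None:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for la, lb in pairs:
        if la not in groups or lb not in groups:
            raise ValueError(f"unknown condition in pair ({la}, {lb})")
        ga, gb = groups[la], groups[lb]
        pct_lower = 100.0 * (ga.mean() - gb.mean()) / ga.mean()
        if ga.size >= 2 and gb.size >= 2 and (ga.var() > 0 or gb.var() > 0):
            cmp_res = welch_ttest(ga, gb, la, lb)
            t, df, p, stars = cmp_res.t, cmp_res.df, cmp_res.p, cmp_res.stars
        else:
            t = df = p = np.nan
            stars = ""
        rows.append(
            {
                "condition_a": la,
                "condition_b": lb,
                "pct_b_lower_than_a": pct_lower,
                "t": t,
                "df": df,
                "p": p,
                "stars": stars,
            }
        )
    comparisons = pd.DataFrame(rows)
    comparisons.attrs["sidedness"] = "two-sided"
    comparisons.attrs["multiple_testing_correction"] = "none"
    return summary, comparisons
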
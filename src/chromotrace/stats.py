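"""Group-comparison statistics used in the report tables.

Closed-form Welch's unequal-variance t-test and one-way ANOVA, with scipy
supplying only the t/F distribution tails, so the numerical surface of the
pipeline is fully testable against resampling oracles.  Significance labels
follow the convention ns (p > 0.05), * (p < 0.05), ** (p < 0.005),
*** (p < 0.0005); no multiple-testing correction is applied — comparisons
are reported per figure/table exactly as computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "GroupComparison", "welch_ttest", "one_way_anova", "significance_stars"]


def significance_stars(p: float) -> str:
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class GroupComparison:
    groups: list[GroupSummary]
    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    stars: str


def _summaries(groups: Sequence[np.ndarray], labels: Sequence[str]) -> list[GroupSummary]:
    return [
        GroupSummary(
            label=str(lab),
            n=len(g),
            mean=float(np.mean(g)),
            sd=float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
        )
        for g, lab in zip(groups, labels)
    ]


def welch_ttest(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("A", "B")
) -> GroupComparison:
    """Two-tailed Welch's t-test (unequal variances).

    t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite degrees of
    freedom.  Degenerate inputs: both groups constant with equal means gives
    (t = 0, p = 1); constant but different means gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        stat = 0.0 if diff == 0.0 else float("inf") * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
        df = float(na + nb - 2)
    else:
        stat = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * float(sps.t.sf(abs(stat), df))
    return GroupComparison(
        groups=_summaries([a, b], labels),
        test="welch_t",
        statistic=float(stat),
        df=float(df),
        p_value=float(p),
        stars=significance_stars(p),
    )


def one_way_anova(
    groups: Sequence[Sequence[float]] | Mapping[str, Sequence[float]],
) -> GroupComparison:
    """One-way ANOVA F-test across ≥ 2 groups.

    F = MS_between/MS_within with (k − 1, N − k) degrees of freedom.  If the
    within-group variance is zero, F is 0 (all group means equal, p = 1) or
    infinite (means differ, p = 0).
    """
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("need >= 2 values per group")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    k = len(arrays)
    n_total = len(all_values)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        stat = 0.0 if ms_between == 0.0 else float("inf")
        p = 1.0 if ms_between == 0.0 else 0.0
    else:
        stat = ms_between / ms_within
        p = float(sps.f.sf(stat, df_between, df_within))
    return GroupComparison(
        groups=_summaries(arrays, labels),
        test="one_way_anova",
        statistic=float(stat),
        df=(float(df_between), float(df_within)),
        p_value=float(p),
        stars=significance_stars(p),
    )
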
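"""Group comparisons in the reporting style of the source experiments.

Two groups are compared with an equal-variance Student's t-test; three or
more with a one-way ANOVA followed by either Tukey's all-pairs or
Dunnett's many-to-one multiple-comparison procedure.  Group means are
always reported with standard errors; alpha is 0.05 and significance is
starred (* p<0.05, ** p<0.01) as in the figure conventions this package
reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupStats", "PairwiseComparison", "ComparisonResult", "compare_groups"]

ALPHA = 0.05


@dataclass
class GroupStats:
    group: str
    n: int
    mean: float
    se: float


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    estimate: float  # mean(a) - mean(b)
    p_value: float
    significant: bool
    stars: str


@dataclass
class ComparisonResult:
    design: str  # "two_group" | "one_way"
    test: str  # "t" | "anova_tukey" | "anova_dunnett"
    groups: list[GroupStats]
    statistic: float  # t for two groups, ANOVA F otherwise
    comparisons: list[PairwiseComparison]
    alpha: float = ALPHA
    anova_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "estimate": c.estimate,
                    "p_value": c.p_value,
                    "significant": c.significant,
                    "stars": c.stars,
                }
                for c in self.comparisons
            ]
        )


def significance_stars(p: float, alpha: float = ALPHA) -> str:
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def _group_stats(name: str, x: np.ndarray) -> GroupStats:
    return GroupStats(
        group=name,
        n=len(x),
        mean=float(x.mean()),
        se=float(x.std(ddof=1) / np.sqrt(len(x))),
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    design: str = "auto",
    posthoc: str = "tukey",
    control: str | None = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare measurement groups.

    Parameters
    ----------
    groups : mapping of group name -> values
        Each group needs at least 2 observations.  The caller decides the
        statistical unit (field, replicate, sample) before pooling.
    design : "auto" | "two_group" | "one_way"
        "auto" picks two_group for 2 groups, one_way otherwise.
    posthoc : "tukey" | "dunnett"
        Multiple-comparison procedure after one-way ANOVA.  Dunnett
        compares every group against ``control``, which must be named.
    """
    names = list(groups)
    data = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("at least 2 groups are required")
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n={len(v)} < 2")
    if design == "auto":
        design = "two_group" if len(names) == 2 else "one_way"
    stats_rows = [_group_stats(k, v) for k, v in data.items()]

    if design == "two_group":
        a, b = (data[n] for n in names)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        comp = PairwiseComparison(
            names[0], names[1], float(a.mean() - b.mean()), float(p), p < alpha,
            significance_stars(p, alpha),
        )
        return ComparisonResult(
            design="two_group", test="t", groups=stats_rows,
            statistic=float(t), comparisons=[comp], alpha=alpha,
        )

    if design != "one_way":
        raise ValueError(f"unknown design {design!r}")
    f_stat, anova_p = sps.f_oneway(*data.values())
    comparisons: list[PairwiseComparison] = []
    if posthoc == "tukey":
        res = sps.tukey_hsd(*data.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p = float(res.pvalue[i, j])
                comparisons.append(
                    PairwiseComparison(
                        names[i], names[j],
                        float(data[names[i]].mean() - data[names[j]].mean()),
                        p, p < alpha, significance_stars(p, alpha),
                    )
                )
        test = "anova_tukey"
    elif posthoc == "dunnett":
        if control is None or control not in data:
            raise ValueError("Dunnett's procedure requires a named control group")
        others = [n for n in names if n != control]
        res = sps.dunnett(*(data[n] for n in others), control=data[control])
        for name, p in zip(others, res.pvalue):
            p = float(p)
            comparisons.append(
                PairwiseComparison(
                    name, control,
                    float(data[name].mean() - data[control].mean()),
                    p, p < alpha, significance_stars(p, alpha),
                )
            )
        test = "anova_dunnett"
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return ComparisonResult(
        design="one_way", test=test, groups=stats_rows,
        statistic=float(f_stat), comparisons=comparisons, alpha=alpha,
        anova_p=float(anova_p),
    )
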
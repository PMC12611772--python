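"""Shared inferential tests: two-sample t, one-way ANOVA with Tukey HSD, and
pairwise Wilcoxon rank-sum with Bonferroni correction.

All p-values are two-sided. Group summaries (mean ± SEM) travel with every
result so cohort tables can be assembled without re-touching the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupSummary",
    "two_sample_t",
    "anova_tukey",
    "wilcoxon_bonferroni",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


@dataclass
class TestResult:
    """A single hypothesis-test outcome (statistic, dof, two-sided p)."""

    method: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    groups: list = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _summaries(groups, labels) -> list:
    out = []
    for label, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        sem = float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan")
        out.append(GroupSummary(label=str(label), n=g.size, mean=float(g.mean()), sem=sem))
    return out


def two_sample_t(a, b, variant: str = "pooled", labels=("a", "b")) -> TestResult:
    """Two-sided two-sample t-test.

    ``variant="pooled"`` assumes equal variances; ``"welch"`` does not.
    Two degenerate zero-variance cases are handled explicitly: equal means give
    the p = 1 convention, unequal means are flagged degenerate (p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant: {variant}")
    summaries = _summaries((a, b), labels)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult("t-test (degenerate)", 0.0, 1.0, df=a.size + b.size - 2,
                              groups=summaries)
        return TestResult("t-test (degenerate)", np.inf, 0.0, df=a.size + b.size - 2,
                          groups=summaries, degenerate=True)
    equal_var = variant == "pooled"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    name = "two-sample t-test (pooled)" if equal_var else "two-sample t-test (Welch)"
    return TestResult(name, float(res.statistic), float(res.pvalue), df=df, groups=summaries)


def anova_tukey(groups, labels=None):
    """One-way ANOVA with Tukey HSD post hoc pairwise comparisons.

    Returns ``(omnibus, pairwise)`` where ``pairwise`` is a list of
    :class:`TestResult`, one per group pair, with studentized-range-adjusted
    p-values. With exactly two groups this delegates to the pooled t-test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        res = two_sample_t(groups[0], groups[1], labels=tuple(labels))
        return res, [res]
    summaries = _summaries(groups, labels)
    if all(np.ptp(g) == 0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
        omnibus = TestResult("one-way ANOVA (degenerate)", 0.0, 1.0,
                             df=(len(groups) - 1, sum(g.size for g in groups) - len(groups)),
                             groups=summaries)
        pairwise = [
            TestResult("Tukey HSD (degenerate)", 0.0, 1.0, groups=[summaries[i], summaries[j]])
            for i, j in combinations(range(len(groups)), 2)
        ]
        return omnibus, pairwise
    f_stat, p = sps.f_oneway(*groups)
    df = (len(groups) - 1, sum(g.size for g in groups) - len(groups))
    omnibus = TestResult("one-way ANOVA", float(f_stat), float(p), df=df, groups=summaries)
    hsd = sps.tukey_hsd(*groups)
    pairwise = []
    for i, j in combinations(range(len(groups)), 2):
        pairwise.append(TestResult(
            "Tukey HSD",
            float(hsd.statistic[i, j]),
            float(hsd.pvalue[i, j]),
            groups=[summaries[i], summaries[j]],
        ))
    return omnibus, pairwise


def wilcoxon_bonferroni(groups, labels=None, exact_max_n: int = 6) -> list:
    """Pairwise Wilcoxon rank-sum tests with Bonferroni correction.

    Small samples (both groups at or below ``exact_max_n``, no ties across the
    pooled sample) use the exact null distribution; larger samples use the
    normal approximation with tie correction. Adjusted p-values are capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(range(len(groups)), 2))
    n_comparisons = len(pairs)
    results = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n and not has_ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        adj = min(1.0, float(res.pvalue) * n_comparisons)
        results.append(TestResult(
            f"Wilcoxon rank-sum ({method}), Bonferroni x{n_comparisons}",
            float(res.statistic), adj,
            groups=_summaries((a, b), (labels[i], labels[j])),
        ))
    return results
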
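"""Cohort summaries and group comparisons (mean +/- SEM conventions).

Test selection: every group is screened with Shapiro-Wilk; if any group
fails at p < 0.05 the rank-based branch is taken.  Two groups: unpaired
t-test or Mann-Whitney U.  More than two: one-way ANOVA with Bonferroni
post hoc, or Kruskal-Wallis with Dunn's post hoc (rank-sum z statistics,
Bonferroni family correction).  Alpha = 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Summary",
    "GroupRow",
    "PairwiseResult",
    "CohortTable",
    "summarize",
    "compare_groups",
    "dunn_test",
]

ALPHA = 0.05


@dataclass
class Summary:
    mean: float
    sem: float
    n: int


def summarize(values) -> Summary:
    """Mean, SEM (SD/sqrt(n), ddof=1) and n; SEM is NaN for a single value."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if x.size == 1:
        warnings.warn("SEM undefined for a single value", stacklevel=2)
        return Summary(mean=float(x[0]), sem=float("nan"), n=1)
    return Summary(
        mean=float(x.mean()),
        sem=float(x.std(ddof=1) / np.sqrt(x.size)),
        n=int(x.size),
    )


@dataclass
class GroupRow:
    label: str
    mean: float
    sem: float
    n: int
    normality_p: float
    normal: bool


@dataclass
class PairwiseResult:
    label_a: str
    label_b: str
    test: str
    p_raw: float
    p_adjusted: float


@dataclass
class CohortTable:
    rows: list
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: list = field(default_factory=list)
    parametric: bool = True


def dunn_test(samples: Sequence[np.ndarray]) -> list:
    """Dunn's post hoc z tests on pooled ranks with tie correction.

    Returns raw two-sided p-values for every pair (i, j), i < j.
    """
    pooled = np.concatenate(samples)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        start += s.size
    out = []
    for i, j in combinations(range(len(samples)), 2):
        se = np.sqrt(var_base * (1.0 / samples[i].size + 1.0 / samples[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((i, j, float(z), float(min(p, 1.0))))
    return out


def compare_groups(samples: Dict[str, Sequence], alpha: float = ALPHA) -> CohortTable:
    """Compare >= 2 labeled samples following the normality-gated scheme."""
    labels = list(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for lab, x in zip(labels, arrays):
        if x.size < 3:
            raise ValueError(f"group {lab!r} has n={x.size} < 3")

    rows = []
    all_normal = True
    for lab, x in zip(labels, arrays):
        if np.ptp(x) == 0:
            p_norm = 0.0  # constant sample: not testable, treat as non-normal
        else:
            p_norm = float(sps.shapiro(x).pvalue)
        is_norm = p_norm >= alpha
        all_normal &= is_norm
        s = summarize(x)
        rows.append(
            GroupRow(
                label=lab, mean=s.mean, sem=s.sem, n=s.n,
                normality_p=p_norm, normal=is_norm,
            )
        )

    pairwise = []
    if len(arrays) == 2:
        if all_normal:
            res = sps.ttest_ind(arrays[0], arrays[1])
            name = "unpaired t-test"
        else:
            res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            name = "Mann-Whitney U"
        p = float(res.pvalue)
        stat = float(res.statistic)
        pairwise.append(
            PairwiseResult(labels[0], labels[1], name, p, p)
        )
        return CohortTable(rows, name, stat, p, pairwise, parametric=all_normal)

    m = len(arrays) * (len(arrays) - 1) // 2
    if all_normal:
        f = sps.f_oneway(*arrays)
        name = "one-way ANOVA + Bonferroni"
        for i, j in combinations(range(len(arrays)), 2):
            t = sps.ttest_ind(arrays[i], arrays[j])
            p_raw = float(t.pvalue)
            pairwise.append(
                PairwiseResult(
                    labels[i], labels[j], "t-test (Bonferroni)",
                    p_raw, min(1.0, p_raw * m),
                )
            )
        return CohortTable(
            rows, name, float(f.statistic), float(f.pvalue), pairwise, parametric=True
        )
    kw = sps.kruskal(*arrays)
    name = "Kruskal-Wallis + Dunn"
    for i, j, z, p_raw in dunn_test(arrays):
        pairwise.append(
            PairwiseResult(
                labels[i], labels[j], "Dunn (Bonferroni)", p_raw, min(1.0, p_raw * m)
            )
        )
    return CohortTable(
        rows, name, float(kw.statistic), float(kw.pvalue), pairwise, parametric=False
    )
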
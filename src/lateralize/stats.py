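"""Group-comparison statistics: thin wrappers over standard routines.

Supported tests mirror the ones used for the figure-level comparisons:
unpaired t, Mann-Whitney, Wilcoxon signed-rank, chi-square, KS,
Kruskal-Wallis with Dunn's post hoc, and one-way ANOVA with Tukey-Kramer
post hoc.  Dunn's test is implemented here (rank-sum z statistics with tie
correction and Bonferroni adjustment); Tukey-Kramer comes from statsmodels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    n_per_group: tuple
    posthoc: Optional[dict] = None
    extra: dict = field(default_factory=dict)


SUPPORTED_TESTS = (
    "t", "mannwhitney", "wilcoxon", "chi2", "ks", "kruskal", "anova",
)


def dunn_posthoc(groups: Sequence[np.ndarray],
                 labels: Optional[Sequence] = None) -> dict:
    """Dunn's post hoc z-tests on pooled ranks after Kruskal-Wallis.

    Two-sided p-values with tie correction, Bonferroni-adjusted across all
    pairwise comparisons.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None else list(range(len(groups)))
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    m = len(groups) * (len(groups) - 1) // 2
    out = {}
    for (a, b) in combinations(range(len(groups)), 2):
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
                     * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
        out[(labels[a], labels[b])] = dict(z=float(z), pvalue=float(p))
    return out


def group_compare(test: str, groups: Sequence[np.ndarray],
                  labels: Optional[Sequence] = None,
                  posthoc: bool = True) -> TestResult:
    """Run a named standard test on the given groups.

    ``chi2`` expects a contingency table (2D array) as the single "group".
    Post hoc procedures (Dunn for kruskal, Tukey-Kramer for anova) run when
    more than two groups are supplied.
    """
    if test not in SUPPORTED_TESTS:
        raise ValueError(
            f"unsupported test {test!r}; supported: {', '.join(SUPPORTED_TESTS)}")
    if test == "chi2":
        table = np.asarray(groups[0] if len(groups) == 1 else groups, dtype=float)
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return TestResult("chi2", float(chi2), float(p),
                          tuple(int(x) for x in table.sum(axis=1)),
                          extra=dict(dof=int(dof)))
    gs = [np.asarray(g, dtype=float) for g in groups]
    ns = tuple(g.size for g in gs)
    if test == "t":
        r = stats.ttest_ind(gs[0], gs[1])
        return TestResult("t", float(r.statistic), float(r.pvalue), ns)
    if test == "mannwhitney":
        r = stats.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
        return TestResult("mannwhitney", float(r.statistic), float(r.pvalue), ns)
    if test == "wilcoxon":
        r = stats.wilcoxon(gs[0], gs[1]) if len(gs) > 1 else stats.wilcoxon(gs[0])
        return TestResult("wilcoxon", float(r.statistic), float(r.pvalue), ns)
    if test == "ks":
        r = stats.ks_2samp(gs[0], gs[1])
        return TestResult("ks", float(r.statistic), float(r.pvalue), ns)
    if test == "kruskal":
        r = stats.kruskal(*gs)
        ph = dunn_posthoc(gs, labels) if posthoc and len(gs) > 2 else None
        return TestResult("kruskal", float(r.statistic), float(r.pvalue), ns,
                          posthoc=ph)
    # anova
    r = stats.f_oneway(*gs)
    ph = None
    if posthoc and len(gs) > 2:
        labels = list(labels) if labels is not None else list(range(len(gs)))
        values = np.concatenate(gs)
        codes = np.concatenate([[str(labels[k])] * g.size
                                for k, g in enumerate(gs)])
        tk = pairwise_tukeyhsd(values, codes)
        ph = {}
        for row in tk.summary().data[1:]:
            ph[(row[0], row[1])] = dict(meandiff=float(row[2]),
                                        pvalue=float(row[3]))
    return TestResult("anova", float(r.statistic), float(r.pvalue), ns,
                      posthoc=ph)
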
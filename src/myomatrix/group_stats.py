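"""Hierarchical per-cell summaries and the group-comparison decision tree.

Cells, not myofibrils, are the unit of replication: every overall mean and
standard error is computed over cell means. Group comparisons follow a fixed
gated procedure: for more than two groups, one-way ANOVA with a
Brown-Forsythe variance-equality gate choosing between Tukey's HSD (equal
variances) and Dunn's rank z-tests with family-wise correction (unequal);
for two groups, a Shapiro-Wilk normality gate choosing between the two-sided
independent t-test and the independent-samples rank-sum test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import VolumeError

__all__ = ["CellSummary", "GroupComparisonResult", "superplot_table", "compare_groups"]

ALPHA = 0.05


@dataclass(frozen=True)
class CellSummary:
    cell_id: str
    group: str
    values: tuple[float, ...]
    cell_mean: float


@dataclass(frozen=True)
class GroupComparisonResult:
    groups: tuple[str, ...]
    group_means: dict[str, float]
    group_sems: dict[str, float | None]
    omnibus_test: str
    omnibus_p: float | None
    variance_test_p: float | None
    normality_ps: dict[str, float] | None
    chosen_branch: str  # tukey | dunn | t_test | rank_sum | descriptive
    pairwise_p: dict[tuple[str, str], float]
    alpha: float = ALPHA

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise_p.items() if p < self.alpha]


def superplot_table(values, cell_ids, group: str = "all"):
    """Collapse per-myofibril values to per-cell means and their mean +/- SE.

    Returns ``(summaries, overall_mean, overall_se)``; the SE is over cell
    means (``sd / sqrt(n_cells)``) and ``None`` for a single cell.
    """
    values = list(values)
    cell_ids = list(cell_ids)
    if len(values) != len(cell_ids):
        raise VolumeError("every value must be tagged with a cell id")
    if not values:
        raise VolumeError("superplot_table requires at least one value")
    if any(c is None for c in cell_ids):
        raise VolumeError("every value must be tagged with a cell id")
    df = pd.DataFrame({"cell": cell_ids, "value": values})
    summaries = [
        CellSummary(str(cid), group, tuple(sub["value"]), float(sub["value"].mean()))
        for cid, sub in df.groupby("cell", sort=True)
    ]
    means = np.array([s.cell_mean for s in summaries])
    overall = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else None
    return summaries, overall, se


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Classic Dunn z-tests on mean ranks, Bonferroni-corrected over all pairs."""
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = stats.rankdata(pooled)  # average ranks: deterministic tie handling
    n = pooled.size
    mean_ranks, sizes, offset = {}, {}, 0
    for name in names:
        k = groups[name].size
        mean_ranks[name] = ranks[offset: offset + k].mean()
        sizes[name] = k
        offset += k
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    n_pairs = len(names) * (len(names) - 1) // 2
    out = {}
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = float(min(1.0, p * n_pairs))
    return out


def compare_groups(groups: dict[str, "np.ndarray | list"], seed: int | None = None) -> GroupComparisonResult:
    """Compare named sets of cell means with the gated decision tree.

    ``seed`` is accepted for interface stability; every branch is
    deterministic (ties resolved by average ranks).
    """
    del seed  # deterministic throughout
    if len(groups) < 2:
        raise VolumeError("compare_groups requires at least 2 groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise VolumeError(f"group {name!r} is empty")
        arrays[name] = arr
    names = tuple(sorted(arrays))
    group_means = {n: float(arrays[n].mean()) for n in names}
    group_sems = {
        n: (float(arrays[n].std(ddof=1) / np.sqrt(arrays[n].size)) if arrays[n].size > 1 else None)
        for n in names
    }
    if any(arrays[n].size < 2 for n in names):
        return GroupComparisonResult(
            names, group_means, group_sems, "none", None, None, None,
            "descriptive", {},
        )

    if len(names) > 2:
        f_stat, anova_p = stats.f_oneway(*(arrays[n] for n in names))
        bf_stat, bf_p = stats.levene(*(arrays[n] for n in names), center="median")
        if bf_p < ALPHA:
            branch = "dunn"
            pairwise = _dunn_pairwise({n: arrays[n] for n in names})
        else:
            branch = "tukey"
            res = stats.tukey_hsd(*(arrays[n] for n in names))
            pairwise = {
                (names[i], names[j]): float(res.pvalue[i, j])
                for i, j in itertools.combinations(range(len(names)), 2)
            }
        return GroupComparisonResult(
            names, group_means, group_sems, "one_way_anova", float(anova_p),
            float(bf_p), None, branch, pairwise,
        )

    a, b = names
    normality = {}
    for n in names:
        arr = arrays[n]
        if arr.size >= 3 and np.ptp(arr) > 0:
            normality[n] = float(stats.shapiro(arr).pvalue)
        else:  # Shapiro-Wilk undefined for n < 3 or constant data
            normality[n] = 1.0
    if all(p >= ALPHA for p in normality.values()):
        branch = "t_test"
        stat, p = stats.ttest_ind(arrays[a], arrays[b])
        if np.isnan(p):  # identical constant groups
            p = 1.0
    else:
        branch = "rank_sum"
        stat, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
    return GroupComparisonResult(
        names, group_means, group_sems, branch, float(p), None, normality,
        branch, {(a, b): float(p)},
    )
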
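"""Group comparisons for Timer metrics with the sample-QC audit trail.

Percentage and locus-fraction metrics are compared with rank tests
(Mann-Whitney U for two groups, Kruskal-Wallis with Dunn's post hoc for
more); continuous metrics (mean angle, MFI) with Student's t-test or
one-way ANOVA with Tukey's HSD.  The module's own contribution is the
QC/exclusion bookkeeping: samples failing the minimum Timer-positive
cell count (default 20) are removed *before* any test runs and the
exclusions are recorded with the rule that removed them.  The tests
themselves delegate to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .locus import DEFAULT_MIN_N, LocusSummary

__all__ = ["GroupComparison", "compare_groups", "summaries_to_table", "dunn_posthoc"]

TESTS = ("mann_whitney", "kruskal_wallis_dunn", "t_test", "anova_tukey")


@dataclass
class GroupComparison:
    """Result of one metric's group comparison with its exclusion audit."""

    metric: str
    test: str
    statistic: float
    pvalue: float
    groups: dict[str, np.ndarray]
    pairwise: pd.DataFrame | None
    excluded: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "group_sizes": {g: int(len(v)) for g, v in self.groups.items()},
            "pairwise": None if self.pairwise is None else self.pairwise.to_dict("records"),
            "excluded": self.excluded,
        }


def summaries_to_table(
    summaries: Sequence[LocusSummary], groups: dict[str, str], metric: str
) -> pd.DataFrame:
    """Tidy (sample, group, value, n_positive) table from locus summaries.

    ``metric`` may be "mean_angle", "mean_blue_mfi", "mean_red_mfi",
    "n_positive" or "frac_<Locus>".  ``groups`` maps sample label ->
    group name.
    """
    rows = []
    for s in summaries:
        if s.label not in groups:
            continue
        if metric.startswith("frac_"):
            value = s.fractions[metric.removeprefix("frac_")]
        else:
            value = getattr(s, metric)
        rows.append(
            {
                "sample": s.label,
                "group": groups[s.label],
                "value": value,
                "n_positive": s.n_positive,
                "qc_included": s.qc_included,
                "min_n": s.min_n,
            }
        )
    return pd.DataFrame(rows)


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    For each pair, z = (mean-rank difference) / sqrt((N(N+1)/12 - T) *
    (1/n_i + 1/n_j)) with the standard tie correction
    T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values are then
    multiplicity-adjusted (Bonferroni by default).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    idx = 0
    mean_ranks, sizes = {}, {}
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[idx : idx + n].mean()
        sizes[g] = n
        idx += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for g1, g2 in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


def _apply_qc(table: pd.DataFrame, min_n: int) -> tuple[pd.DataFrame, list[dict]]:
    excluded = []
    if "n_positive" in table.columns:
        bad = table["n_positive"] < min_n
        for _, row in table[bad].iterrows():
            excluded.append(
                {
                    "sample": row.get("sample", "?"),
                    "group": row["group"],
                    "n_positive": int(row["n_positive"]),
                    "rule": f"min_n={min_n}",
                }
            )
        table = table[~bad]
    return table, excluded


def compare_groups(
    table: pd.DataFrame,
    test: str,
    metric: str = "value",
    min_n: int = DEFAULT_MIN_N,
) -> GroupComparison:
    """Compare a metric between groups after the sample-QC exclusion.

    ``table`` needs columns group and value (plus n_positive for the QC
    rule to apply, and optionally sample for the audit).  Supported
    tests: mann_whitney, t_test (two groups), kruskal_wallis_dunn,
    anova_tukey (two or more groups).
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    table, excluded = _apply_qc(table, min_n)
    all_groups = pd.unique(table["group"]) if len(table) else []
    groups = {g: table.loc[table["group"] == g, "value"].to_numpy(dtype=float) for g in all_groups}
    empty = [g for g in groups if len(groups[g]) == 0]
    pre_qc_groups = {e["group"] for e in excluded}
    fully_excluded = pre_qc_groups - set(groups)
    if empty or fully_excluded:
        raise ValueError(
            f"groups with no remaining samples after QC: {sorted(set(empty) | fully_excluded)}"
        )
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = list(groups.values())
    pairwise = None

    if test == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
    elif test == "t_test":
        if len(arrays) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        stat, p = sps.ttest_ind(*arrays)
    elif test == "kruskal_wallis_dunn":
        stat, p = sps.kruskal(*arrays)
        pairwise = dunn_posthoc(groups)
    else:  # anova_tukey
        stat, p = sps.f_oneway(*arrays)
        values = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(groups[g]) for g in groups])
        tk = pairwise_tukeyhsd(values, labels)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )

    return GroupComparison(
        metric=metric,
        test=test,
        statistic=float(stat),
        pvalue=float(p),
        groups=groups,
        pairwise=pairwise,
        excluded=excluded,
    )
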
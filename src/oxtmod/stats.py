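"""Nonparametric group comparisons used throughout the analyses.

Paired data use the Wilcoxon signed-rank test, independent samples the
Wilcoxon rank-sum test, and multi-group comparisons the Kruskal-Wallis
test followed by Tukey-Kramer-corrected pairwise comparisons on mean ranks
(the studentized-range criterion applied to the rank sums). One-sided
alternatives are available where a directional hypothesis exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["compare_groups", "ComparisonResult"]

METHODS = ("wilcoxon_signed_rank", "wilcoxon_rank_sum", "kruskal_wallis_tukey_kramer")


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    degenerate: bool = False
    #: pairwise Tukey-Kramer-adjusted p-values (multi-group mode only)
    pairwise: pd.DataFrame | None = field(default=None)


def _rank_sum_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer comparisons on mean ranks after a Kruskal-Wallis test."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    # tie correction for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    var_base = n_total * (n_total + 1) / 12.0 * tie_term

    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            q = abs(mean_ranks[a] - mean_ranks[b]) / se * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, np.inf))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_rank_a": mean_ranks[a],
                    "mean_rank_b": mean_ranks[b],
                    "p_adjusted": min(max(p, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    values_a,
    values_b=None,
    groups: dict[str, np.ndarray] | None = None,
    paired: bool = False,
    sides: str = "two-sided",
    method: str | None = None,
) -> ComparisonResult:
    """Nonparametric comparison of two samples or several groups.

    Two-sample mode takes ``values_a``/``values_b`` (``paired`` selects the
    signed-rank test); multi-group mode takes ``groups`` (name -> values)
    and returns the Kruskal-Wallis statistic plus all pairwise adjusted
    p-values. ``sides`` in {"two-sided", "greater", "less"} applies to the
    two-sample tests. All-tied paired differences are a documented
    degenerate case: statistic NaN, p 1.0, ``degenerate`` True.
    """
    if groups is not None or method == "kruskal_wallis_tukey_kramer":
        if groups is None or len(groups) < 2:
            raise ValueError("multi-group mode needs a groups mapping with >= 2 groups")
        arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        stat, p = sps.kruskal(*arrays.values())
        return ComparisonResult(
            "kruskal_wallis_tukey_kramer", float(stat), float(p), pairwise=_rank_sum_pairwise(arrays)
        )

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method is None:
        method = "wilcoxon_signed_rank" if paired else "wilcoxon_rank_sum"
    if method == "wilcoxon_signed_rank":
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonResult(method, float("nan"), 1.0, degenerate=True)
        stat, p = sps.wilcoxon(a, b, alternative=sides)
        return ComparisonResult(method, float(stat), float(p))
    if method == "wilcoxon_rank_sum":
        stat, p = sps.ranksums(a, b, alternative=sides)
        return ComparisonResult(method, float(stat), float(p))
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
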
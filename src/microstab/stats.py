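"""Rank-based two-group comparisons and multiple-testing adjustment.

Wraps the Mann-Whitney/Wilcoxon rank-sum test with an explicit
exact-vs-normal-approximation switch (exact for small tie-free samples)
and Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("microstab")

#: largest per-group n for which the exact null is enumerated
EXACT_MAX_N = 12

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p: float
    method: str  # "exact" or "normal-approx"
    p_adjusted: float | None = None


def wilcoxon_rank_sum(
    x, y, group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    The exact null distribution is enumerated when both groups have at
    most 12 observations and the pooled data are tie-free; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties
    method = "exact" if exact else "normal-approx"
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    logger.debug(
        "rank-sum %s vs %s (n=%d,%d): %s method", group_a, group_b, x.size, y.size, method
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(x.size),
        n_b=int(y.size),
        U=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method=method,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    values: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise rank-sum comparisons between the groups of a long table."""
    groups = list(dict.fromkeys(values[group_col]))
    comps = [
        wilcoxon_rank_sum(
            values.loc[values[group_col] == ga, value_col],
            values.loc[values[group_col] == gb, value_col],
            group_a=str(ga),
            group_b=str(gb),
        )
        for ga, gb in itertools.combinations(groups, 2)
    ]
    out = pd.DataFrame(
        {
            "group_a": [c.group_a for c in comps],
            "group_b": [c.group_b for c in comps],
            "n_a": [c.n_a for c in comps],
            "n_b": [c.n_b for c in comps],
            "U": [c.U for c in comps],
            "p": [c.p for c in comps],
            "method": [c.method for c in comps],
        }
    )
    if adjust and len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
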
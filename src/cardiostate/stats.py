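"""Non-parametric group comparisons and attribute screening.

Paired awake-vs-anaesthetised contrasts use the Wilcoxon signed-rank
test (zero differences discarded), between-agent contrasts the unpaired
Wilcoxon rank-sum (Mann-Whitney) test, and attribute screening the
two-sample Kolmogorov-Smirnov test: a physiological variable is kept as
a classifier attribute if any pairwise group difference is significant
at alpha = 0.05.  All p-values are two-sided; exact distributions are
used for small samples, normal/asymptotic approximations beyond.  No
multiple-testing correction is applied (per-variable reporting).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import AllZeroDifferences, GroupTooSmall, LengthMismatch

__all__ = [
    "ComparisonResult",
    "paired_wilcoxon",
    "rank_sum",
    "ks_two_sample",
    "ks_select",
    "summary_table",
]

EXACT_N_MAX = 25  # exact signed-rank distribution up to this n (no ties)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    test: str
    n: tuple[int, ...]


def paired_wilcoxon(before: np.ndarray, after: np.ndarray) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (the classical zero-discard
    convention); the exact null distribution is used for n <= 25 when no
    ties are present, the normal approximation otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise LengthMismatch(f"{before.size} vs {after.size}")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        raise AllZeroDifferences("every paired difference is zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= EXACT_N_MAX and not has_ties) else "approx"
    res = sp_stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test="wilcoxon-signed-rank",
        n=(int(d.size),),
    )


def rank_sum(a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U) test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    small = a.size <= 20 and b.size <= 20
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test="wilcoxon-rank-sum",
        n=(int(a.size), int(b.size)),
    )


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test (exact for small samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = sp_stats.ks_2samp(a, b, method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test="kolmogorov-smirnov",
        n=(int(a.size), int(b.size)),
    )


def ks_select(
    features_by_group: pd.DataFrame,
    group_col: str = "state",
    alpha: float = 0.05,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Screen attributes by between-group Kolmogorov-Smirnov tests.

    Parameters
    ----------
    features_by_group : DataFrame
        One row per subject-state; one column per attribute plus a group
        label column.
    mode : {"pairwise", "awake_vs_anaes"}
        "pairwise" keeps an attribute if any pairwise group comparison is
        significant; "awake_vs_anaes" pools the non-awake groups and
        compares against "awake" only.

    Returns
    -------
    DataFrame with columns ``attribute`` and ``min_p`` for the selected
    attributes, ordered by ascending ``min_p``.
    """
    groups = features_by_group[group_col]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise GroupTooSmall("need >= 2 groups")
    counts = groups.value_counts()
    if (counts < 5).any():
        raise GroupTooSmall(f"need >= 5 subjects per group, got {counts.to_dict()}")
    if alpha <= 0:
        return pd.DataFrame({"attribute": [], "min_p": []})

    if mode == "pairwise":
        pairs = list(combinations(labels, 2))
    elif mode == "awake_vs_anaes":
        pairs = [("awake", "__anaes__")]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    attrs = [c for c in features_by_group.columns if c != group_col]
    rows = []
    for attr in attrs:
        pvals = []
        for g1, g2 in pairs:
            a = features_by_group.loc[groups == g1, attr].to_numpy()
            if g2 == "__anaes__":
                b = features_by_group.loc[groups != "awake", attr].to_numpy()
            else:
                b = features_by_group.loc[groups == g2, attr].to_numpy()
            if np.array_equal(np.sort(a), np.sort(b)):
                pvals.append(1.0)
            else:
                pvals.append(ks_two_sample(a, b).p_value)
        min_p = min(pvals)
        if min_p < alpha:
            rows.append({"attribute": attr, "min_p": min_p})
    out = pd.DataFrame(rows, columns=["attribute", "min_p"])
    return out.sort_values("min_p", kind="stable").reset_index(drop=True)


def summary_table(values: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Cohort summary: mean (SD) per state and the four headline p-values.

    ``values`` has one row per subject-state with columns ``subject``,
    ``agent`` (sevoflurane/propofol), ``state`` (awake/anaes) and one
    column per variable.  For each variable the table reports mean (SD)
    for the awake and anaesthetised recordings of each agent arm, the
    paired signed-rank p within each arm, and unpaired rank-sum p-values
    comparing the two arms' awake (p_controls) and anaesthetised
    (p_sevo_prop) measurements.
    """
    if variables is None:
        variables = [c for c in values.columns if c not in ("subject", "agent", "state")]
    rows = []
    for var in variables:
        row: dict[str, float | str] = {"variable": var}
        arm_values = {}
        for agent in ("sevoflurane", "propofol"):
            arm = values[values["agent"] == agent].sort_values("subject")
            aw = arm.loc[arm["state"] == "awake", var].to_numpy()
            an = arm.loc[arm["state"] == "anaes", var].to_numpy()
            arm_values[agent] = (aw, an)
            prefix = "sevo" if agent == "sevoflurane" else "prop"
            row[f"{prefix}_control_mean"] = aw.mean()
            row[f"{prefix}_control_sd"] = aw.std(ddof=1) if aw.size > 1 else 0.0
            row[f"{prefix}_anaes_mean"] = an.mean()
            row[f"{prefix}_anaes_sd"] = an.std(ddof=1) if an.size > 1 else 0.0
            try:
                row[f"p_{prefix}"] = paired_wilcoxon(aw, an).p_value
            except AllZeroDifferences:
                row[f"p_{prefix}"] = 1.0
        row["p_controls"] = rank_sum(arm_values["sevoflurane"][0], arm_values["propofol"][0]).p_value
        row["p_sevo_prop"] = rank_sum(arm_values["sevoflurane"][1], arm_values["propofol"][1]).p_value
        rows.append(row)
    return pd.DataFrame(rows)
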
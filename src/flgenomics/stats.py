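"""Group-comparison statistics for cohort reporting.

Continuous variables (signature exposures, K1 contributions) are compared
between two groups by the two-sided Mann-Whitney/Wilcoxon rank-sum test:
exact by full enumeration of group assignments when both groups have at
most ``exact_max_n`` observations (ties handled naturally, since the
statistic is computed on the actual values), otherwise by the tie-corrected
normal approximation.  Categorical variables use the chi-square test or
Fisher's exact test on the contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu, rankdata


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    grouping: str
    test: str             # "rank-sum" / "chi-square" / "fisher"
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of group x vs y with midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def rank_sum_exact(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Enumerates every choice of which pooled observations form group one and
    computes P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|) under the null of
    exchangeability.  Handles ties (and zero-variance groups: all
    assignments are then equally extreme and p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mean_u)
    # midranks are a property of the pooled values, so U for any assignment
    # is just the rank sum of the chosen indices minus n1(n1+1)/2
    ranks = rankdata(pooled).tolist()
    offset = n1 * (n1 + 1) / 2.0
    count = total = 0
    for chosen in combinations(ranks, n1):
        u = sum(chosen) - offset
        if abs(u - mean_u) >= dev_obs - 1e-9:  # tolerance for float rank arithmetic
            count += 1
        total += 1
    return u_obs, count / total


def rank_sum(x, y, exact_max_n: int = 10) -> tuple[float, float, str]:
    """Two-sided rank-sum test; exact for small groups, else tie-corrected normal.

    Returns (U, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        u, p = rank_sum_exact(x, y)
        return u, p, "exact"
    # plain tie-corrected normal approximation (no continuity correction:
    # the corrected variant is measurably conservative at moderate n)
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue), "asymptotic"


def compare_groups(
    values,
    groups,
    variable: str = "value",
    grouping: str = "group",
    test: str = "rank-sum",
    exact_max_n: int = 10,
) -> GroupComparison:
    """Compare a variable between groups with the appropriate test.

    ``test`` is one of ``"rank-sum"`` (continuous, exactly 2 groups),
    ``"chi-square"`` or ``"fisher"`` (categorical; values are category
    labels and the contingency table is groups x categories — Fisher
    requires a 2x2 table).
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) < 2 or any((groups == g).sum() == 0 for g in names):
        raise ValueError("need >= 2 non-empty groups")
    if test == "rank-sum":
        if len(names) != 2:
            raise ValueError("rank-sum comparison requires exactly 2 groups")
        x = values[groups == names[0]].astype(float)
        y = values[groups == names[1]].astype(float)
        u, p, _ = rank_sum(x, y, exact_max_n)
        return GroupComparison(variable, grouping, "rank-sum", u, p, (len(x), len(y)))
    cats = sorted(set(values.tolist()))
    table = np.array(
        [[(values[groups == g] == c).sum() for c in cats] for g in names], dtype=int
    )
    if test == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = fisher_exact(table)
        return GroupComparison(
            variable, grouping, "fisher", float(odds), float(p),
            tuple(int(t) for t in table.sum(axis=1)),
        )
    if test == "chi-square":
        chi2, p, _, _ = chi2_contingency(table)
        return GroupComparison(
            variable, grouping, "chi-square", float(chi2), float(p),
            tuple(int(t) for t in table.sum(axis=1)),
        )
    raise ValueError(f"unknown test {test!r}")
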
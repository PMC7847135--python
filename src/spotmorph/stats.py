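"""Nonparametric descriptives and Kruskal–Wallis group comparisons.

The feature distributions are skewed and heavy-tailed, so location and
spread are summarized by median, quartiles and range, and group differences
are tested with the rank-based Kruskal–Wallis H (tie-corrected, chi-square
approximation with k-1 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class Descriptives:
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n: int


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    group_ns: tuple[int, ...]
    feature: str = ""


def descriptives(values) -> Descriptives:
    """Median, quartiles (linear interpolation) and range; NaNs are dropped."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no values after missing-value removal")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear (type-7) rule
    return Descriptives(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(arr.min()),
        max=float(arr.max()),
        n=int(arr.size),
    )


def _h_statistic(pooled: np.ndarray, ns: np.ndarray) -> float:
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.concatenate([[0], np.cumsum(ns)])
    rank_sums = np.array([ranks[offsets[i] : offsets[i + 1]].sum() for i in range(len(ns))])
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(rank_sums**2 / ns) - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    return float(h / correction)


def _exact_permutation_p(pooled: np.ndarray, ns: np.ndarray, h_obs: float) -> float:
    """Exhaustive permutation p-value: enumerate every split of the pooled
    observations into groups of the given sizes and count H >= H_obs."""
    from itertools import combinations

    n_total = pooled.size
    if n_total > 12:
        raise ValueError("exact permutation p-value is limited to N <= 12")
    count = total = 0

    def recurse(remaining: tuple, gi: int, chosen: list):
        nonlocal count, total
        if gi == len(ns) - 1:
            perm = np.concatenate(chosen + [pooled[list(remaining)]])
            total += 1
            if _h_statistic(perm, ns) >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(remaining, int(ns[gi])):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, gi + 1, chosen + [pooled[list(combo)]])

    recurse(tuple(range(n_total)), 0, [])
    return count / total


def kruskal_wallis(groups: list, feature: str = "", p_method: str = "chi2") -> KWResult:
    """Tie-corrected Kruskal–Wallis H test across k groups.

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / [1 - sum(t^3 - t)/(N^3 - N)]
    with R_i the rank sums (mid-ranks for ties) and t the tie multiplicities;
    p comes from the chi-square upper tail with k-1 degrees of freedom
    (``p_method="chi2"``) or, for very small samples where the asymptotic
    tail is unreliable, from exhaustive enumeration of all group
    assignments (``p_method="exact"``, N <= 12).  All-tied data yield H = 0
    by convention.
    """
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size:
            cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("kruskal_wallis needs at least 2 non-empty groups")
    ns = np.array([len(g) for g in cleaned])
    pooled = np.concatenate(cleaned)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("kruskal_wallis needs at least 3 observations in total")
    df = len(cleaned) - 1
    if np.ptp(pooled) == 0:  # every observation tied: H defined as 0
        return KWResult(H=0.0, df=df, p=1.0, group_ns=tuple(int(n) for n in ns), feature=feature)
    h = _h_statistic(pooled, ns)
    if p_method == "exact":
        p = _exact_permutation_p(pooled, ns, h)
    elif p_method == "chi2":
        p = float(sps.chi2.sf(h, df))
    else:
        raise ValueError("p_method must be 'chi2' or 'exact'")
    return KWResult(H=float(h), df=df, p=p, group_ns=tuple(int(n) for n in ns), feature=feature)


def descriptives_table(features: pd.DataFrame, group_col: str = "group", columns=None) -> pd.DataFrame:
    """Per-feature, per-group descriptive statistics as a tidy table."""
    columns = columns or [c for c in features.columns if features[c].dtype.kind == "f"]
    rows = []
    for feat in columns:
        for grp, sub in features.groupby(group_col, sort=True):
            vals = sub[feat].dropna()
            if vals.empty:
                continue
            d = descriptives(vals)
            rows.append(
                {
                    "feature": feat,
                    "group": grp,
                    "n": d.n,
                    "median": d.median,
                    "q1": d.q1,
                    "q3": d.q3,
                    "min": d.min,
                    "max": d.max,
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis_table(
    features: pd.DataFrame,
    group_col: str = "group",
    columns=None,
    holm: bool = False,
) -> pd.DataFrame:
    """Kruskal–Wallis H per feature across groups (raw p by default).

    ``holm=True`` appends Holm-adjusted p-values; the raw per-feature tests
    remain the primary report.
    """
    columns = columns or [c for c in features.columns if features[c].dtype.kind == "f"]
    rows = []
    for feat in columns:
        groups = [sub[feat].dropna().to_numpy() for _, sub in features.groupby(group_col, sort=True)]
        groups = [g for g in groups if g.size]
        if len(groups) < 2:
            continue
        res = kruskal_wallis(groups, feature=feat)
        rows.append(
            {
                "feature": feat,
                "H": res.H,
                "df": res.df,
                "p": res.p,
                "n": int(sum(res.group_ns)),
            }
        )
    table = pd.DataFrame(rows)
    if holm and not table.empty:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_holm"] = adj
    return table
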
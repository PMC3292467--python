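"""Small-sample two-group statistics: descriptive summaries, two-sided
Wilcoxon rank-sum tests (normal approximation and exact enumeration), and
SVM-RFE feature ranking.

The normal approximation applies, by default, NO continuity correction and
NO tie correction:

    W = rank sum of the smaller group (midranks for ties)
    z = (W - m(N+1)/2) / sqrt(m * n * (N+1) / 12)
    p = 2 * Phi(-|z|)

With groups of sizes 4 and 5 this convention reproduces published
rank-configuration p-values (0.0275, 0.05, 0.4624, 0.8065) to four decimals.
Both corrections are available as flags.  The exact test enumerates all
C(m+n, m) group assignments and is used as an oracle for the approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "GroupSummary",
    "WilcoxonResult",
    "FeatureRanking",
    "summarize",
    "wilcoxon_ranksum_normal",
    "wilcoxon_ranksum_exact",
    "compare_groups",
    "svm_rfe_rank",
    "PARAMETER_COLUMNS",
    "SIGNIFICANCE_LEVEL",
]

#: the eight per-animal parameters compared between groups.
PARAMETER_COLUMNS = ("VB", "K1", "k2", "k3", "k4", "RBP", "SUV", "FD")

SIGNIFICANCE_LEVEL = 0.05

_EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupSummary:
    """Mean / SD / median / min / max block for one parameter in one group."""

    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "median": self.median,
            "minimum": self.minimum, "maximum": self.maximum, "n": self.n,
        }


def summarize(values) -> GroupSummary:
    """Descriptive summary; SD uses the n-1 denominator (0 for n = 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        minimum=float(np.min(arr)),
        maximum=float(np.max(arr)),
        n=int(arr.size),
    )


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum test outcome; W is the smaller group's rank sum."""

    rank_sum_w: float
    z: float
    p_two_sided: float
    method: str  # "normal_approx" or "exact"

    def to_dict(self) -> dict:
        return {"W": self.rank_sum_w, "z": self.z,
                "p": self.p_two_sided, "method": self.method}


def _pooled_ranks(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of the pooled sample, split back into the two groups."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    return ranks[: a.size], ranks[a.size:]


def _smaller_first(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (a, b) if a.size <= b.size else (b, a)


def wilcoxon_ranksum_normal(
    a,
    b,
    continuity: bool = False,
    tie_correction: bool = False,
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test, normal approximation.

    By default neither a continuity correction nor a tie correction is
    applied (see module docstring); both can be enabled.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    small, large = _smaller_first(a, b)
    ranks_small, _ = _pooled_ranks(small, large)
    m, n = small.size, large.size
    n_tot = m + n
    w = float(np.sum(ranks_small))
    mean_w = m * (n_tot + 1) / 2.0
    var_w = m * n * (n_tot + 1) / 12.0
    if tie_correction:
        pooled = np.concatenate([small, large])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / ((n_tot) * (n_tot - 1))
        var_w = m * n / 12.0 * ((n_tot + 1) - tie_term)
    if var_w <= 0:
        return WilcoxonResult(rank_sum_w=w, z=0.0, p_two_sided=1.0,
                              method="normal_approx")
    diff = w - mean_w
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var_w)
    p = float(min(2.0 * norm.sf(abs(z)), 1.0))
    return WilcoxonResult(rank_sum_w=w, z=float(z), p_two_sided=p,
                          method="normal_approx")


def wilcoxon_ranksum_exact(a, b) -> WilcoxonResult:
    """Exact two-sided rank-sum test by full enumeration.

    Two-sided p = P(|W - E[W]| >= |w_obs - E[W]|) over all C(m+n, m) equally
    likely assignments of the pooled midranks to the smaller group.  Only
    feasible for m + n <= 12.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    small, large = _smaller_first(a, b)
    m, n = small.size, large.size
    n_tot = m + n
    if n_tot > _EXACT_MAX_N:
        raise ValueError(
            f"exact enumeration limited to {_EXACT_MAX_N} observations; "
            "use wilcoxon_ranksum_normal"
        )
    ranks_small, ranks_large = _pooled_ranks(small, large)
    pooled_ranks = np.concatenate([ranks_small, ranks_large])
    w_obs = float(np.sum(ranks_small))
    mean_w = m * (n_tot + 1) / 2.0
    obs_dev = abs(w_obs - mean_w)
    hits = 0
    total = comb(n_tot, m)
    for idx in combinations(range(n_tot), m):
        w = float(np.sum(pooled_ranks[list(idx)]))
        if abs(w - mean_w) >= obs_dev - 1e-9:
            hits += 1
    p = hits / total
    var_w = m * n * (n_tot + 1) / 12.0
    z = (w_obs - mean_w) / np.sqrt(var_w) if var_w > 0 else 0.0
    return WilcoxonResult(rank_sum_w=w_obs, z=float(z), p_two_sided=p,
                          method="exact")


def compare_groups(
    table: pd.DataFrame,
    group_column: str = "group",
    parameters: tuple[str, ...] = PARAMETER_COLUMNS,
    method: str = "normal_approx",
    continuity: bool = False,
    tie_correction: bool = False,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Per-parameter two-group rank-sum comparison.

    ``table`` holds one row per animal with a group label column and one
    column per parameter.  Returns a table with W, z, p and a significance
    star per parameter.
    """
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise ValueError(f"parameter table is missing columns: {missing}")
    groups = sorted(table[group_column].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    ga = table[table[group_column] == groups[0]]
    gb = table[table[group_column] == groups[1]]
    rows = []
    for p in parameters:
        a = ga[p].to_numpy(float)
        b = gb[p].to_numpy(float)
        if method == "exact":
            res = wilcoxon_ranksum_exact(a, b)
        else:
            res = wilcoxon_ranksum_normal(
                a, b, continuity=continuity, tie_correction=tie_correction
            )
        rows.append(
            {
                "parameter": p,
                "W": res.rank_sum_w,
                "z": res.z,
                "p": res.p_two_sided,
                "significant": res.p_two_sided < alpha,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FeatureRanking:
    """SVM-RFE output: best-first feature order and per-round diagnostics."""

    ranked_features: list[str]
    elimination_order: list[str]
    weight_squares: list[dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "ranked_features": self.ranked_features,
            "elimination_order": self.elimination_order,
            "weight_squares": self.weight_squares,
        }


def svm_rfe_rank(features: pd.DataFrame, labels) -> FeatureRanking:
    """Recursive feature elimination ranked by squared linear-SVM weights.

    Features are z-scored internally; a hard/soft-margin linear SVM (C = 1,
    deterministic solver) is trained on the surviving features each round and
    the feature with the smallest squared weight is eliminated.  Constant
    features are eliminated first, with a warning.
    """
    from sklearn.svm import SVC

    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, found {classes.tolist()}")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError("need at least two animals per group")
    names = list(features.columns)
    x = features.to_numpy(float)

    elimination: list[str] = []
    weight_rounds: list[dict[str, float]] = []

    sd = x.std(axis=0, ddof=0)
    constant = [names[j] for j in range(len(names)) if sd[j] == 0]
    if constant:
        warnings.warn(
            f"constant features eliminated before ranking: {constant}",
            RuntimeWarning,
            stacklevel=2,
        )
        elimination.extend(constant)

    surviving = [nm for nm in names if nm not in constant]
    y = (labels == classes[1]).astype(int)
    while surviving:
        if len(surviving) == 1:
            elimination.append(surviving.pop())
            break
        cols = [names.index(nm) for nm in surviving]
        xs = x[:, cols]
        mu = xs.mean(axis=0)
        sigma = xs.std(axis=0, ddof=0)
        xs = (xs - mu) / sigma
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(xs, y)
        w2 = np.ravel(clf.coef_) ** 2
        weight_rounds.append(dict(zip(surviving, map(float, w2))))
        drop = int(np.argmin(w2))
        elimination.append(surviving.pop(drop))

    ranked = list(reversed(elimination))
    return FeatureRanking(
        ranked_features=ranked,
        elimination_order=elimination,
        weight_squares=weight_rounds,
    )
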
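"""Univariate and distance-based hypothesis tests.

Covers the statistical toolbox used around the aggregated-impact index:

* one-way ANOVA per timepoint (model ``Y_ij = mu + treatment_i +
  residual_ij``) with Tukey HSD pairwise follow-up,
* PERMANOVA on a distance matrix (pseudo-F from squared inter-point
  distances, free permutation of group labels), overall and pairwise with
  optional Benjamini-Hochberg adjustment,
* sequential (Type-I) variance partitioning of a response against an ordered
  set of numeric predictors, reporting per-term sums of squares, mean
  squares, F against the residual, and percent of total SS.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "permanova",
    "pairwise_permanova",
    "variance_partition",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def _split_groups(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups differ in length")
    split = {g: values[groups == g] for g in pd.unique(groups)}
    if len(split) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in split.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return split


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA F test.

    A zero within-group mean square with non-zero between-group variation is
    reported as an infinite F with p = 0.
    """
    split = _split_groups(values, groups)
    all_vals = np.concatenate(list(split.values()))
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in split.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in split.values())
    df_b = len(split) - 1
    df_w = all_vals.size - len(split)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(
        F=float(f),
        df_between=df_b,
        df_within=df_w,
        p=float(stats.f.sf(f, df_b, df_w)),
    )


def tukey_hsd(values: Sequence[float], groups: Sequence, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey honest-significant-difference test for all group pairs.

    The studentized-range statistic for groups i, j is

        q_ij = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))

    (Tukey-Kramer for unequal group sizes), with p from the studentized
    range distribution on (k groups, residual df).
    """
    split = _split_groups(values, groups)
    k = len(split)
    df_w = sum(v.size for v in split.values()) - k
    ms_w = sum(((v - v.mean()) ** 2).sum() for v in split.values()) / df_w
    rows = []
    for a, b in itertools.combinations(sorted(split, key=str), 2):
        va, vb = split[a], split[b]
        se = math.sqrt(ms_w / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        diff = abs(va.mean() - vb.mean())
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "label_a": a,
                "label_b": b,
                "statistic": q,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def _permanova_stat(d2: np.ndarray, group_idx: list[np.ndarray], n: int, a: int) -> float:
    # d2: squared distances; SS from the Huygens identity on pairwise distances
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for idx in group_idx:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    *,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p-value.

    ``dm`` is a square symmetric distance matrix (array, DataFrame, or
    scikit-bio DistanceMatrix) aligned with ``groups``. The Monte-Carlo
    p-value is (number of permuted F >= observed + 1) / (n_permutations + 1)
    under free permutation of the raw labels. ``exhaustive=True`` enumerates
    every distinct labelling instead (the observed one included), giving
    p = #{F_perm >= F_obs} / #labellings.
    """
    d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    groups = np.asarray(groups)
    n = d.shape[0]
    if groups.shape[0] != n:
        raise ValueError("groups length must match distance matrix size")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    a = len(labels)
    d2 = d * d

    def stat(perm_groups: np.ndarray) -> float:
        idx = [np.flatnonzero(perm_groups == g) for g in labels]
        return _permanova_stat(d2, idx, n, a)

    f_obs = stat(groups)
    if exhaustive:
        seen: set[tuple] = set()
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            labelling = tuple(groups[list(perm)])
            if labelling in seen:
                continue
            seen.add(labelling)
            total += 1
            if stat(np.asarray(labelling)) >= f_obs - 1e-12:
                count += 1
        return f_obs, count / total

    rng = np.random.default_rng(seed)
    if math.isinf(f_obs):
        return f_obs, 1.0 / (n_permutations + 1)
    count = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(groups)) >= f_obs - 1e-12:
            count += 1
    return f_obs, (count + 1) / (n_permutations + 1)


def pairwise_permanova(
    dm,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    adjust: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """PERMANOVA restricted to every unordered pair of groups.

    ``adjust="BH"`` applies Benjamini-Hochberg correction across the pairs;
    the ``significant`` flag tests the (adjusted, if requested) p at
    ``alpha``.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}; use 'none' or 'BH'")
    d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups), key=str)
    seeds = np.random.SeedSequence(seed).generate_state(
        len(labels) * (len(labels) - 1) // 2
    )
    rows = []
    for s, (ga, gb) in zip(seeds, itertools.combinations(labels, 2)):
        idx = np.flatnonzero((groups == ga) | (groups == gb))
        sub = d[np.ix_(idx, idx)]
        f, p = permanova(sub, groups[idx], n_permutations, int(s % (2**31)))
        rows.append({"label_a": ga, "label_b": gb, "statistic": f, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "BH":
        out["adjusted_p"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["adjusted_p"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def variance_partition(
    response: Sequence[float], predictors: dict[str, Sequence[float]]
) -> pd.DataFrame:
    """Sequential (Type-I) least-squares decomposition of the response
    variance over an ordered set of single-df numeric predictors.

    Terms enter the model in the dict's order; each term row reports its SS,
    MS (= SS for one df), F against the residual MS, percent of total SS, and
    significance stars (* p<0.05, *** p<0.001). The final ``residual`` row
    carries the residual MS, df, and remaining percent. A predictor collinear
    with earlier terms contributes (numerically) zero SS and is flagged with
    a warning by the underlying fit.
    """
    y = np.asarray(response, dtype=float)
    names = list(predictors)
    x = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in predictors.items()})
    if len(x) != y.size:
        raise ValueError("response and predictors differ in length")
    if y.size < len(names) + 2:
        raise ValueError("need at least (number of terms + 2) observations")

    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        warnings.warn(
            "collinear predictor(s): some terms contribute zero degrees of freedom",
            stacklevel=2,
        )
    ss_total = float(((y - y.mean()) ** 2).sum())
    df_resid = int(fit.df_resid)
    ss_resid = float(fit.ssr)
    ms_resid = ss_resid / df_resid if df_resid > 0 else math.nan

    # sequential SS: reduction in residual SS as each term enters in order
    rows = []
    prev_ssr = ss_total
    for i, name in enumerate(names):
        sub = sm.OLS(y, sm.add_constant(x[names[: i + 1]])).fit()
        ss_term = max(prev_ssr - float(sub.ssr), 0.0)
        prev_ssr = float(sub.ssr)
        f = ss_term / ms_resid if ms_resid and ms_resid > 0 else math.inf
        p = float(stats.f.sf(f, 1, df_resid)) if math.isfinite(f) else 0.0
        rows.append(
            {
                "term": name,
                "sum_sq": ss_term,
                "mean_sq": ss_term,
                "F": f,
                "p": p,
                "percent": 100.0 * ss_term / ss_total if ss_total > 0 else 0.0,
                "stars": _stars(p),
                "df": 1,
            }
        )
    rows.append(
        {
            "term": "residual",
            "sum_sq": ss_resid,
            "mean_sq": ms_resid,
            "F": math.nan,
            "p": math.nan,
            "percent": 100.0 * ss_resid / ss_total if ss_total > 0 else 0.0,
            "stars": "",
            "df": df_resid,
        }
    )
    return pd.DataFrame(rows)
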
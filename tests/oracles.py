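"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and the scikit-bio diversity
routines) used by the package: tree metrics are computed by explicit branch
enumeration over the tree topology, PERMANOVA sums of squares by literal
double loops over pairs, and the letter display is validated against the raw
pairwise interval-overlap relation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tree_branches(tree):
    """[(branch_length, frozenset of descendant leaf names)] for every
    non-root node, by structural traversal."""
    out = []
    for node in tree.traverse(include_self=False):
        leaves = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        out.append((float(node.length or 0.0), leaves))
    return out


def faith_pd_naive(counts: dict, tree) -> float:
    observed = {k for k, v in counts.items() if v > 0}
    return sum(l for l, leaves in tree_branches(tree) if leaves & observed)


def unweighted_unifrac_naive(a: dict, b: dict, tree) -> float:
    obs_a = {k for k, v in a.items() if v > 0}
    obs_b = {k for k, v in b.items() if v > 0}
    unique = shared = 0.0
    for l, leaves in tree_branches(tree):
        in_a, in_b = bool(leaves & obs_a), bool(leaves & obs_b)
        if in_a and in_b:
            shared += l
        elif in_a or in_b:
            unique += l
    total = unique + shared
    return unique / total if total > 0 else 0.0


def weighted_unifrac_naive(a: dict, b: dict, tree, normalized: bool) -> float:
    ta, tb = sum(a.values()), sum(b.values())
    num = den = 0.0
    for l, leaves in tree_branches(tree):
        pa = sum(a.get(k, 0) for k in leaves) / ta if ta else 0.0
        pb = sum(b.get(k, 0) for k in leaves) / tb if tb else 0.0
        num += l * abs(pa - pb)
        den += l * (pa + pb)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


def permanova_f_naive(d: np.ndarray, groups) -> float:
    """Pseudo-F from literal pairwise sums (independent of the package's
    matrix-slice implementation)."""
    groups = list(groups)
    n = len(groups)
    labels = sorted(set(groups), key=str)
    a = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        s = 0.0
        for i, j in itertools.combinations(idx, 2):
            s += d[i, j] ** 2
        ss_within += s / len(idx)
    if ss_within == 0.0:
        return math.inf if ss_total > ss_within else 0.0
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_p_naive(d: np.ndarray, groups) -> float:
    """Exact permutation p by enumerating every distinct labelling."""
    f_obs = permanova_f_naive(d, groups)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if permanova_f_naive(d, perm) >= f_obs - 1e-12:
            hits += 1
    return hits / total


def overlap_relation(intervals) -> np.ndarray:
    """Closed-interval pairwise overlap matrix."""
    n = len(intervals)
    rel = np.zeros((n, n), dtype=bool)
    for i, (lo_i, hi_i) in enumerate(intervals):
        for j, (lo_j, hi_j) in enumerate(intervals):
            rel[i, j] = not (hi_i < lo_j or hi_j < lo_i)
    return rel


def hedges_g_naive(control, treated) -> tuple[float, float]:
    """Straight-line re-evaluation of the g and var(g) formulas."""
    c = np.asarray(control, float)
    t = np.asarray(treated, float)
    nc, nt = len(c), len(t)
    m = nc + nt - 2
    sp = math.sqrt(((nt - 1) * t.std(ddof=1) ** 2 + (nc - 1) * c.std(ddof=1) ** 2) / m)
    g = (1 - 3 / (4 * m - 1)) * (t.mean() - c.mean()) / sp
    var = (nt + nc) / (nt * nc) + g**2 / (2 * (nt + nc))
    return g, var
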
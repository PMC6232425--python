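"""Community composition and diversity metrics for OTU count tables.

Samples are rows of an OTU table (columns = OTU ids, integer counts) with a
matching rooted phylogeny whose leaves are the OTU ids. The module covers the
standard amplicon workflow: dataset-wide singleton removal, rarefaction to a
common depth, alpha diversity (observed species, Simpson's reciprocal 1/sum
p_i^2, Faith's phylogenetic diversity), phylogeny-aware beta diversity
(unweighted and weighted UniFrac, raw or normalized), and principal
coordinates analysis of the resulting distance matrices.

Faith's PD follows the root-inclusive convention (the minimal subtree always
contains the root), and weighted UniFrac defaults to the raw, non-normalized
form; both match the classic QIIME pipeline behaviour. Phylogenetic metrics
are delegated to scikit-bio.
"""

from __future__ import annotations

import io
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "remove_singletons",
    "rarefy_counts",
    "rarefy_table",
    "observed_species",
    "simpson_reciprocal",
    "faith_pd",
    "unifrac",
    "distance_matrix",
    "alpha_diversity_table",
    "pcoa",
]

UNIFRAC_METRICS = (
    "unweighted_unifrac",
    "weighted_unifrac",
    "weighted_normalized_unifrac",
)


def read_otu_table(path) -> pd.DataFrame:
    """Read a tab-separated OTU table (first column OTU ids, remaining
    columns per-sample integer counts) into a samples x OTUs frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T.astype(np.int64)


def write_otu_table(table: pd.DataFrame, path) -> None:
    """Write a samples x OTUs frame as an OTUs x samples TSV."""
    table.T.to_csv(path, sep="\t", index_label="otu_id")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def remove_singletons(table: pd.DataFrame) -> pd.DataFrame:
    """Drop OTUs whose total count over ALL samples is exactly 1.

    The singleton criterion is dataset-wide: an OTU seen once in a single
    sample is removed everywhere, while one seen once in each of two samples
    (total 2) is retained.
    """
    totals = table.sum(axis=0)
    return table.loc[:, totals != 1]


def rarefy_counts(counts: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Subsample one sample's counts to exactly ``depth`` without replacement
    (multivariate hypergeometric draw). OTUs drawn to zero keep a 0 entry."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() < depth:
        raise ValueError("sample below rarefaction depth")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Rarefy every sample of the table to ``depth``; one draw per sample,
    with per-sample seeds derived deterministically from ``seed``."""
    shallow = table.index[table.sum(axis=1) < depth].tolist()
    if shallow:
        raise ValueError(
            f"sample below rarefaction depth {depth}: {shallow}"
        )
    seeds = np.random.SeedSequence(seed).spawn(len(table.index))
    out = {
        sample: np.random.default_rng(s).multivariate_hypergeometric(
            table.loc[sample].to_numpy(dtype=np.int64), depth
        )
        for sample, s in zip(table.index, seeds)
    }
    return pd.DataFrame.from_dict(out, orient="index", columns=table.columns)


def observed_species(counts) -> int:
    """Number of OTUs with a positive count (richness)."""
    arr = np.asarray(counts)
    if arr.sum() == 0:
        warnings.warn("all-zero sample: observed species is 0", stacklevel=2)
        return 0
    return int(np.count_nonzero(arr > 0))


def simpson_reciprocal(counts) -> float:
    """Simpson's reciprocal evenness index 1 / sum_i p_i^2.

    The plug-in estimator is the default; ``k`` equally abundant OTUs give
    exactly ``k``.
    """
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("zero total count")
    p = arr / total
    return float(1.0 / np.sum(p * p))


def _check_leaves(otu_ids: Sequence[str], counts, tree: TreeNode) -> None:
    observed = {o for o, c in zip(otu_ids, np.asarray(counts)) if c > 0}
    leaves = {t.name for t in tree.tips()}
    missing = observed - leaves
    if missing:
        raise ValueError(f"observed OTU(s) missing from tree: {sorted(missing)}")


def faith_pd(counts, otu_ids: Sequence[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree connecting the observed OTUs and the root."""
    _check_leaves(otu_ids, counts, tree)
    return float(_skbio_faith_pd(np.asarray(counts), list(otu_ids), tree))


def unifrac(
    counts_a,
    counts_b,
    otu_ids: Sequence[str],
    tree: TreeNode,
    *,
    weighted: bool = True,
    normalized: bool = False,
) -> float:
    """UniFrac dissimilarity between two samples over a shared OTU list.

    Unweighted: unique branch length / total branch length spanned by either
    community. Weighted raw: sum_i b_i |p_i^A - p_i^B| over branches, p = the
    fraction of a sample's reads descending from the branch; the normalized
    variant divides by sum_i b_i (p_i^A + p_i^B). ``normalized`` is ignored
    for the unweighted metric (it is normalized by construction).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both profiles empty")
    _check_leaves(otu_ids, a, tree)
    _check_leaves(otu_ids, b, tree)
    if weighted:
        return float(
            weighted_unifrac(a, b, list(otu_ids), tree, normalized=normalized)
        )
    return float(unweighted_unifrac(a, b, list(otu_ids), tree))


def distance_matrix(table: pd.DataFrame, tree: TreeNode, metric: str) -> DistanceMatrix:
    """All pairwise UniFrac distances for a samples x OTUs table."""
    if metric not in UNIFRAC_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {', '.join(UNIFRAC_METRICS)}"
        )
    return beta_diversity(
        metric,
        table.to_numpy(dtype=float),
        ids=list(table.index),
        taxa=list(table.columns),
        tree=tree,
    )


def alpha_diversity_table(table: pd.DataFrame, tree: TreeNode) -> pd.DataFrame:
    """Observed species, Simpson's reciprocal, and Faith's PD per sample."""
    otu_ids = list(table.columns)
    rows = {}
    for sample in table.index:
        counts = table.loc[sample].to_numpy()
        rows[sample] = {
            "observed_species": observed_species(counts),
            "simpson_reciprocal": simpson_reciprocal(counts),
            "faith_pd": faith_pd(counts, otu_ids, tree),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def pcoa(dm: DistanceMatrix | pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates analysis (classical metric scaling).

    Double-centres -D^2/2, eigendecomposes, and returns coordinates for the
    positive-eigenvalue axes ordered by descending eigenvalue, plus the full
    eigenvalue spectrum (negative eigenvalues are reported but their axes
    dropped). Axis signs are fixed by making each axis's largest-magnitude
    loading positive.
    """
    if isinstance(dm, DistanceMatrix):
        d = np.asarray(dm.data, dtype=float)
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        ids = list(dm.index) if isinstance(dm, pd.DataFrame) else [
            str(i) for i in range(len(d))
        ]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0)) if n else 0.0
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for k in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
    )
    frame.index.name = "sample_id"
    return frame, eigvals
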
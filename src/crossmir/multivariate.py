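"""Sample-level structure: Spearman/complete-linkage clustering, chi-square
branch enrichment, and PCA with loading-based miRNA ranking.

Samples are clustered on the distance d(a, b) = 1 - Spearman rho between
their expression profiles, with complete-linkage agglomeration; cutting the
top merge yields two branches whose composition is tested against a binary
sample class (e.g. MNA vs non-MNA) with a Pearson chi-square on the 2x2
table.  PCA is a singular value decomposition of the per-variable-centered
expression matrix (no unit-variance scaling); miRNAs are ranked by absolute
loading to identify the variables driving each component.

Spearman distances depend only on within-sample ranks, so the tree is
invariant to any strictly monotone transform of expression.  The default
expression transform for both analyses is log2(NRQ); raw NRQ and centered
Ct are available as alternatives (only PCA is affected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import spearmanr

from .preprocess import NormalizedMatrix

__all__ = [
    "ClusterPartition",
    "EnrichmentResult",
    "PCAResult",
    "expression_matrix",
    "spearman_distance_matrix",
    "hierarchical_cluster",
    "cut_two_branches",
    "enrichment_chi2",
    "pca",
    "rank_loadings",
    "top_loading_overlap",
    "linkage_to_newick",
]


@dataclass
class ClusterPartition:
    """Complete-linkage tree over samples plus (optionally) a two-branch cut.

    ``linkage`` is a scipy linkage matrix; ``branch_of`` maps sample id to
    branch 1 or 2 after :func:`cut_two_branches` (branch 1 contains the
    first sample in input order).
    """

    linkage: np.ndarray
    sample_ids: list[str]
    distance_metric: str = "1 - Spearman rho"
    branch_of: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class EnrichmentResult:
    """Pearson chi-square on the branch x class 2x2 table (1 df)."""

    table: pd.DataFrame
    chi2: float
    p_value: float
    enriched_branch: int
    class_fraction: dict[int, float]


@dataclass
class PCAResult:
    """SVD-based PCA: sample scores, orthonormal variable loadings,
    explained-variance fractions (non-increasing, summing to 1 when all
    components are retained)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_var: np.ndarray


def expression_matrix(
    n: NormalizedMatrix,
    transform: Literal["log2_nrq", "nrq", "centered_ct"] = "log2_nrq",
) -> pd.DataFrame:
    """Samples-by-miRNAs expression matrix under the chosen transform."""
    if transform == "centered_ct":
        return n.centered_ct.T
    if n.nrq is None:
        raise ValueError("NRQ not computed")
    if transform == "nrq":
        return n.nrq.T
    if transform == "log2_nrq":
        return np.log2(n.nrq).T
    raise ValueError(f"unknown transform {transform!r}")


def spearman_distance_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distance 1 - Spearman rho over expression profiles.

    ``expr`` is samples x variables; needs >= 3 variables.  A sample with a
    constant profile has no defined rank correlation and is reported as an
    error naming the sample.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 variables for rank correlation")
    X = expr.to_numpy(dtype=float)
    constant = expr.index[np.ptp(X, axis=1) == 0.0].tolist()
    if constant:
        raise ValueError(f"constant expression profile for samples: {constant}")
    rho, _ = spearmanr(X.T)
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.index, columns=expr.index)


def hierarchical_cluster(
    d: pd.DataFrame,
    method: str = "complete",
) -> ClusterPartition:
    """Agglomerate samples from a distance matrix (complete linkage default).

    Deterministic given input ordering.  Raises on a non-symmetric input.
    """
    D = d.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    Z = linkage(squareform(D, checks=False), method=method)
    return ClusterPartition(
        linkage=Z,
        sample_ids=[str(s) for s in d.index],
        distance_metric="1 - Spearman rho",
    )


def cut_two_branches(partition: ClusterPartition) -> ClusterPartition:
    """Cut the top merge into two branches; branch 1 holds the first sample.

    Returns the partition with ``branch_of`` populated.
    """
    if len(partition.sample_ids) < 2:
        raise ValueError("need at least 2 samples to cut")
    flat = fcluster(partition.linkage, t=2, criterion="maxclust")
    first = flat[0]
    branch_of = {
        s: (1 if c == first else 2)
        for s, c in zip(partition.sample_ids, flat)
    }
    partition.branch_of = branch_of
    return partition


def enrichment_chi2(
    partition: ClusterPartition,
    labels: Mapping[str, str] | pd.Series,
    *,
    yates: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square (1 df) of class composition across the two branches.

    Tests the observed branch x class frequencies against the expected
    random distribution; no continuity correction unless ``yates=True``
    (expected counts in 2x2 tables like these can be small — documented,
    not silently corrected).  Raises on a zero marginal.
    """
    if not partition.branch_of:
        raise ValueError("partition has no branch assignment; run cut_two_branches")
    lab = pd.Series({s: labels[s] for s in partition.sample_ids})
    classes = sorted(set(lab))
    if len(classes) != 2:
        raise ValueError(f"labels must define exactly two classes, found {classes}")
    table = pd.DataFrame(
        0, index=pd.Index([1, 2], name="branch"), columns=pd.Index(classes, name="class")
    )
    for s in partition.sample_ids:
        table.loc[partition.branch_of[s], lab[s]] += 1
    O = table.to_numpy(dtype=float)
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in the 2x2 table")
    E = row @ col / O.sum()
    diff = np.abs(O - E)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / E).sum())
    p = float(chi2_dist.sf(stat, df=1))
    frac = {b: float(table.loc[b, classes[0]] / table.loc[b].sum()) for b in (1, 2)}
    enriched = 1 if frac[1] >= frac[2] else 2  # branch above the marginal rate of class[0]
    return EnrichmentResult(table=table, chi2=stat, p_value=p,
                            enriched_branch=enriched, class_fraction=frac)


def pca(expr: pd.DataFrame) -> PCAResult:
    """PCA of a samples x variables matrix via SVD of the centered data.

    Columns (variables) are mean-centered; no unit-variance scaling.  Sign
    convention: each loading column's largest-magnitude element is positive.
    Explained-variance fractions cover all min(n_samples, n_variables)
    components and sum to 1.
    """
    if expr.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2
    total = var.sum()
    explained = var / total if total > 0 else var
    comps = [f"PC{j + 1}" for j in range(S.size)]
    scores = pd.DataFrame(U * S, index=expr.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=expr.columns, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, explained_var=explained)


def rank_loadings(p: PCAResult, component: str | int, top_n: int = 20) -> list[str]:
    """Variables sorted by |loading| on one component, descending; name breaks ties.

    Truncates with a warning when ``top_n`` exceeds the variable count.
    """
    comp = component if isinstance(component, str) else f"PC{component}"
    if comp not in p.loadings.columns:
        raise KeyError(f"component {comp!r} not in PCA result")
    col = p.loadings[comp]
    if top_n > len(col):
        warnings.warn(
            f"top_n={top_n} exceeds {len(col)} variables; returning all", stacklevel=2
        )
        top_n = len(col)
    order = sorted(col.index, key=lambda v: (-abs(col[v]), str(v)))
    return [str(v) for v in order[:top_n]]


def top_loading_overlap(
    p: PCAResult, component_a: str | int, component_b: str | int, top_n: int = 20
) -> int:
    """Count variables common to the top-n |loading| lists of two components."""
    a = set(rank_loadings(p, component_a, top_n))
    b = set(rank_loadings(p, component_b, top_n))
    return len(a & b)


def linkage_to_newick(partition: ClusterPartition) -> str:
    """Serialize the sample dendrogram as a Newick string with branch lengths."""
    tree = to_tree(partition.linkage)
    labels = partition.sample_ids

    def walk(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.10g}"

    return walk(tree, tree.dist) + ";"
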
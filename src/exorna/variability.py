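"""Interindividual variability: Spearman correlations and sample clustering.

Samples are compared pairwise by the Spearman correlation of their
(normalized) expression, clustered hierarchically on 1 - rho with average
linkage, and the within-cell vs within-exosome correlation distributions
are contrasted with a two-sided Wilcoxon rank-sum test.  The pairwise
correlations share samples and are therefore dependent; the test is
reported as-is with that caveat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._data import CELL, EXOSOME


def spearman_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation between sample columns.

    Average ranks for ties; a constant sample vector has undefined
    correlation and yields NaN entries for its pairs.
    """
    if expression.shape[1] < 2 or expression.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 transcripts")
    with warnings.catch_warnings():
        # constant sample vectors are handled below by flagging NaN
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(expression.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    const = expression.std(axis=0).to_numpy() == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=expression.columns, columns=expression.columns)


def cluster_samples(correlations: pd.DataFrame):
    """Average-linkage agglomerative clustering on distance 1 - rho.

    Returns (linkage matrix, leaf order as sample IDs).
    """
    if correlations.isna().any().any():
        bad = list(correlations.index[correlations.isna().any(axis=1)])
        raise ValueError(f"NA correlations; remove samples first: {bad}")
    dist = 1.0 - correlations.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = [correlations.index[i] for i in hierarchy.leaves_list(linkage)]
    return linkage, leaves


def cut_two_clusters(linkage, sample_ids) -> dict[str, int]:
    """Membership of the two-cluster cut, as sample -> {0, 1}."""
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust") - 1
    return dict(zip(sample_ids, (int(v) for v in labels)))


def dendrogram_newick(linkage, leaf_names) -> str:
    """Serialise a SciPy linkage as a Newick string with merge heights."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


@dataclass
class VariabilityComparison:
    mean_within_cell: float
    mean_within_exosome: float
    n_cell_pairs: int
    n_exosome_pairs: int
    statistic: float
    pvalue: float
    note: str = (
        "pairwise correlations share samples and are not independent; "
        "the rank-sum p-value is reported for comparability only"
    )


def _within_pairs(correlations: pd.DataFrame, ids: list[str]) -> np.ndarray:
    sub = correlations.loc[ids, ids].to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    return sub[iu]


def compare_within_compartment_variability(
    correlations: pd.DataFrame, samples: pd.DataFrame
) -> VariabilityComparison:
    """Two-sided Wilcoxon rank-sum on within-compartment correlation pairs.

    Collects the n(n-1)/2 within-cell and within-exosome pairwise rho
    values; the exact null distribution is used for small tie-free groups
    and the tie-corrected normal approximation otherwise.
    """
    meta = samples.loc[correlations.index]
    cell_ids = list(meta.index[meta["compartment"] == CELL])
    exo_ids = list(meta.index[meta["compartment"] == EXOSOME])
    if len(cell_ids) < 2 or len(exo_ids) < 2:
        raise ValueError("each compartment needs >= 2 samples")
    cell_rho = _within_pairs(correlations, cell_ids)
    exo_rho = _within_pairs(correlations, exo_ids)
    pooled = np.concatenate([cell_rho, exo_rho])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and max(len(cell_rho), len(exo_rho)) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(cell_rho, exo_rho, alternative="two-sided", method=method)
    return VariabilityComparison(
        mean_within_cell=float(cell_rho.mean()),
        mean_within_exosome=float(exo_rho.mean()),
        n_cell_pairs=len(cell_rho),
        n_exosome_pairs=len(exo_rho),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )
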
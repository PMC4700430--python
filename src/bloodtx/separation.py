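"""Case-control separation diagnostics: PCA, UPGMA clustering, accuracies.

Samples are the observations and probes the features.  PCA centers the
features but does not rescale them (the values are already log-ratio
like after baselining).  Hierarchical clustering uses Euclidean distance
with average linkage (UPGMA) and a two-cluster cut; the cluster-accuracy
summary takes the better of the two possible cluster-to-group mappings,
so it is always >= 0.5.  "Linear separability" is quantified as the
resubstitution accuracy of the best linear boundary in the PC1-PC2
plane, found exactly by enumerating candidate boundary directions
through pairs of sample points (exhaustive for the small n typical of
matched case-control designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .datatypes import ExpressionMatrix, SampleTable


def pca_samples(matrix: ExpressionMatrix, probe_subset: Optional[Sequence[str]] = None,
                n_components: Optional[int] = None, scale: bool = False
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA over a probe subset.

    Returns (coordinates: samples x components, variance_explained
    fractions, nonincreasing).  Features (probes) are centered; set
    ``scale=True`` for unit-variance scaling.
    """
    if probe_subset is not None:
        if len(probe_subset) == 0:
            raise ValueError("probe subset is empty")
        matrix = matrix.subset_probes(probe_subset)
    if matrix.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = matrix.values.to_numpy().T  # samples x probes
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    k = n_components or min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ClusterResult:
    """UPGMA dendrogram plus its two-cluster cut."""

    linkage: np.ndarray  # scipy linkage matrix over samples
    labels: pd.Series    # sample -> {1, 2}
    newick: str


def hierarchical_cluster(matrix: ExpressionMatrix,
                         probe_subset: Optional[Sequence[str]] = None
                         ) -> ClusterResult:
    """Average-linkage (UPGMA) clustering of samples, Euclidean distance.

    The tree is cut into exactly two clusters; ties in merge order
    follow the deterministic lowest-index convention of the linkage
    implementation.  The dendrogram is also rendered as a Newick string
    with samples as leaves and merge heights as branch lengths.
    """
    if probe_subset is not None:
        matrix = matrix.subset_probes(probe_subset)
    if matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = matrix.values.to_numpy().T
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    newick = _linkage_to_newick(Z, list(matrix.sample_ids))
    return ClusterResult(
        linkage=Z,
        labels=pd.Series(labels, index=matrix.sample_ids, name="cluster"),
        newick=newick,
    )


def _linkage_to_newick(Z: np.ndarray, leaf_names: list) -> str:
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, leaf_names)
    return str(tree).strip()


def classification_accuracy(labels: pd.Series, samples: SampleTable) -> float:
    """Best-mapping concordance between a 2-cluster labelling and groups.

    The maximum over the two possible cluster-to-group assignments of
    the fraction of samples whose cluster maps to their diagnostic
    group; invariant to swapping group labels and always >= 0.5 for a
    genuine two-cluster split.
    """
    groups = samples.groups.loc[labels.index]
    uniq = sorted(labels.unique())
    if len(uniq) == 1:
        freq = groups.value_counts(normalize=True).max()
        warnings.warn(
            "degenerate single-cluster labelling; accuracy = majority "
            "group frequency",
            UserWarning,
            stacklevel=2,
        )
        return float(freq)
    if len(uniq) != 2:
        raise ValueError("expected a two-cluster labelling")
    is_case = (groups == "case").to_numpy()
    in_first = (labels == uniq[0]).to_numpy()
    acc1 = (in_first == is_case).mean()
    return float(max(acc1, 1.0 - acc1))


def linear_separability(coords: pd.DataFrame, samples: SampleTable) -> float:
    """Resubstitution accuracy of the best linear boundary in PC1-PC2.

    The optimal linear classifier in the plane can always be realized
    (up to infinitesimal translation) with a boundary whose direction is
    either parallel or perpendicular to the segment joining two sample
    points, so enumerating projections onto those candidate directions
    and scanning all thresholds is exact.  For n > 200 samples the
    enumeration is skipped in favour of a linear-discriminant boundary.
    """
    if coords.shape[1] < 2:
        raise ValueError("need at least 2 principal components")
    X = coords.iloc[:, :2].to_numpy()
    y = (samples.groups.loc[coords.index] == "case").to_numpy()
    n = len(y)
    if n > 200:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis()
        return float(lda.fit(X, y).score(X, y))
    directions = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    for i in range(n):
        for j in range(i + 1, n):
            d = X[j] - X[i]
            norm = np.hypot(*d)
            if norm == 0:
                continue
            d = d / norm
            directions.append(d)
            directions.append(np.array([-d[1], d[0]]))  # perpendicular
    best = 0.5
    for d in directions:
        proj = X @ d
        order = np.argsort(proj, kind="mergesort")
        sorted_proj = proj[order]
        sorted_case = y[order]
        # below-threshold prefix classified as one class: accuracy for
        # every cut position via cumulative sums, both orientations.
        # Cuts may only fall between strictly different projections —
        # coincident points cannot be separated by a linear boundary.
        prefix_cases = np.concatenate([[0], np.cumsum(sorted_case)])
        total_cases = prefix_cases[-1]
        k = np.arange(n + 1)
        valid = np.ones(n + 1, dtype=bool)
        valid[1:n] = sorted_proj[1:] > sorted_proj[:-1]
        acc_case_low = (prefix_cases + (n - k) - (total_cases - prefix_cases)) / n
        acc_both = np.maximum(acc_case_low, 1.0 - acc_case_low)
        best = max(best, float(acc_both[valid].max()))
    return best


def separation_report(matrix: ExpressionMatrix, samples: SampleTable,
                      probe_subset: Optional[Sequence[str]] = None) -> dict:
    """PCA + clustering + both accuracy summaries for one probe subset."""
    coords, varexp = pca_samples(matrix, probe_subset)
    clust = hierarchical_cluster(matrix, probe_subset)
    return {
        "pc_coordinates": coords,
        "variance_explained": varexp,
        "cluster_labels": clust.labels,
        "newick": clust.newick,
        "cluster_accuracy": classification_accuracy(clust.labels, samples),
        "linear_accuracy": linear_separability(coords, samples),
    }
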
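"""Categorical phenotype assignment by hierarchical clustering.

Samples are clustered on the signature genes with Euclidean distances and
complete linkage (the standard Cluster 3.0 / Treeview protocol for two-group
expression heatmaps), cut into k flat clusters, and clusters are labeled
CS/M or NS/E by their mean signature polarity. With k=3 the middle cluster
is labeled intermediary (I). A consistency audit compares calls for samples
profiled in several datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, MissingGenesError, ValidationError
from .io import ExpressionMatrix
from .labels import CSM, INTERMEDIARY, NSE
from .signature import SignatureGeneList

__all__ = [
    "ClusterResult",
    "PhenotypeCall",
    "hcluster",
    "label_clusters",
    "classify_samples",
    "cross_dataset_consistency",
    "standardize_genes",
]


@dataclass
class ClusterResult:
    """Flat clustering plus the dendrogram it was cut from."""

    assignments: pd.Series           # sample_id -> cluster index (1..k)
    linkage_matrix: np.ndarray       # scipy (n-1) x 4 merge list
    k: int
    linkage: str = "complete"
    metric: str = "euclidean"

    def to_newick(self) -> str:
        """Export the dendrogram as a Newick string with merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        leaves = list(self.assignments.index)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{leaves[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    label: str                       # CS/M, NS/E or I
    basis: str = "clustering"        # "clustering" or "score"


def standardize_genes(values: pd.DataFrame, center_only: bool = False) -> pd.DataFrame:
    """Per-gene z-score across samples (or mean-centering only).

    Genes with zero variance are centered and left unscaled.
    """
    centered = values.sub(values.mean(axis=1), axis=0)
    if center_only:
        return centered
    sd = values.std(axis=1, ddof=1).replace(0.0, 1.0)
    return centered.div(sd, axis=0)


def _signature_submatrix(matrix: ExpressionMatrix, signature: SignatureGeneList,
                         standardize: bool) -> pd.DataFrame:
    missing = set(signature.genes) - set(matrix.feature_ids)
    if missing:
        raise MissingGenesError(missing)
    sub = matrix.values.loc[signature.genes]
    return standardize_genes(sub) if standardize else sub


def hcluster(
    matrix: ExpressionMatrix,
    signature: SignatureGeneList,
    k: int = 2,
    standardize: bool = True,
) -> ClusterResult:
    """Complete-linkage Euclidean clustering of samples on signature genes."""
    if k < 1 or k > matrix.n_samples:
        raise ValidationError(f"k={k} incompatible with {matrix.n_samples} samples")
    sub = _signature_submatrix(matrix, signature, standardize)
    points = sub.to_numpy().T  # samples as observations in gene space
    Z = hierarchy.linkage(points, method="complete", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(flat, index=sub.columns, name="cluster")
    if assignments.nunique() != k:
        raise DegenerateInputError(
            f"requested {k} clusters but only {assignments.nunique()} distinct "
            "groups exist (duplicate samples?)"
        )
    return ClusterResult(assignments, Z, k)


def _polarity_scores(cluster_result: ClusterResult, matrix: ExpressionMatrix,
                     signature: SignatureGeneList) -> pd.Series:
    """Per-cluster mean of (up-arm z) minus (down-arm z)."""
    sub = _signature_submatrix(matrix, signature, standardize=True)
    up = sub.loc[signature.up_genes].mean(axis=0) if signature.up_genes else 0.0
    down = sub.loc[signature.down_genes].mean(axis=0) if signature.down_genes else 0.0
    per_sample = up - down
    return per_sample.groupby(cluster_result.assignments).mean()


def label_clusters(
    cluster_result: ClusterResult,
    matrix: ExpressionMatrix,
    signature: SignatureGeneList,
) -> list[PhenotypeCall]:
    """Name clusters by signature polarity.

    The cluster with the highest mean standardized expression of up-in-CS/M
    genes minus up-in-NS/E genes is CS/M; the lowest is NS/E; with k=3 the
    middle cluster is intermediary (I).
    """
    if cluster_result.k not in (2, 3):
        raise ValidationError("labeling requires k=2 or k=3")
    polarity = _polarity_scores(cluster_result, matrix, signature)
    if polarity.round(12).duplicated().any():
        raise DegenerateInputError("cluster polarity means tie; cannot label")
    ordered = polarity.sort_values(ascending=False)
    names = {ordered.index[0]: CSM, ordered.index[-1]: NSE}
    if cluster_result.k == 3:
        names[ordered.index[1]] = INTERMEDIARY
    return [PhenotypeCall(s, names[c], "clustering")
            for s, c in cluster_result.assignments.items()]


def classify_samples(
    matrix: ExpressionMatrix,
    signature: SignatureGeneList,
    k: int = 2,
    standardize: bool = True,
) -> pd.Series:
    """One-call convenience: cluster then label; returns sample -> label."""
    res = hcluster(matrix, signature, k=k, standardize=standardize)
    calls = label_clusters(res, matrix, signature)
    return pd.Series({c.sample_id: c.label for c in calls}, name="phenotype") \
        .reindex(matrix.sample_ids)


def cross_dataset_consistency(
    calls_by_dataset: dict[str, list[PhenotypeCall]],
) -> tuple[int, int, list[str]]:
    """Audit label agreement for samples profiled in several datasets.

    An *assignment* is each (sample, dataset) call for samples appearing in at
    least two datasets. A sample is *inconsistent* when its non-intermediary
    labels disagree across datasets; all its assignments still count, but the
    sample is reported once.

    Returns ``(n_assignments, n_inconsistent, inconsistent_sample_ids)``.
    """
    per_sample: dict[str, list[str]] = {}
    for calls in calls_by_dataset.values():
        seen = set()
        for call in calls:
            if call.sample_id in seen:
                raise ValidationError(f"duplicate call for {call.sample_id} in one dataset")
            seen.add(call.sample_id)
            per_sample.setdefault(call.sample_id, []).append(call.label)
    shared = {s: labs for s, labs in per_sample.items() if len(labs) >= 2}
    if not shared:
        raise ValidationError("no sample is shared by >= 2 datasets")
    n_assignments = sum(len(labs) for labs in shared.values())
    inconsistent = sorted(
        s for s, labs in shared.items()
        if len({l for l in labs if l != INTERMEDIARY}) > 1
    )
    return n_assignments, len(inconsistent), inconsistent
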
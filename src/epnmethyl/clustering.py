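"""Two-group hierarchical clustering of beta values and PFA/PFB labeling.

Samples are clustered on a marker-probe-restricted beta matrix with Ward
linkage on Euclidean distance (recorded in the assignment's provenance so
alternatives can be configured), the tree is cut at k groups, and — because
PFA is the CpG-island hypermethylated subgroup — the cluster with the higher
mean marker methylation is labeled PFA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import UnresolvedLabelError, ValidationError
from .probes import MarkerSet, validate_beta_matrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Sample -> cluster mapping, optional cluster -> subgroup labels, and
    the linkage settings plus per-cluster mean marker methylation."""

    cluster_of: dict[str, int]
    subgroup_of_cluster: dict[int, str] | None
    linkage_method: str
    distance_metric: str
    cluster_marker_mean: dict[int, float]

    def subgroup_of(self, sample_id: str) -> str:
        if self.subgroup_of_cluster is None:
            raise ValidationError("clusters have not been assigned subgroup labels")
        return self.subgroup_of_cluster[self.cluster_of[sample_id]]

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_of.values()))


def _restricted(matrix: pd.DataFrame, marker_set: MarkerSet) -> pd.DataFrame:
    probes = [p for p in marker_set if p in matrix.index]
    if not probes:
        raise ValidationError("no marker probes present in the matrix")
    sub = matrix.loc[probes]
    # per-probe mean imputation for missing values; all-missing probes dropped
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        logger.info("hierarchical_cluster: imputing %d missing values by probe mean",
                    n_missing)
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
        sub = sub.dropna(axis=0, how="any")
        if sub.empty:
            raise ValidationError("all marker probes entirely missing")
    return sub


def hierarchical_cluster(
    matrix: pd.DataFrame,
    marker_set: MarkerSet,
    k: int = 2,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Agglomerative clustering of samples on the marker-restricted matrix,
    cut at ``k`` groups. Deterministic for fixed input; cluster indices are
    renumbered by order of first appearance in the sample order."""
    validate_beta_matrix(matrix)
    n = matrix.shape[1]
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} samples available")
    sub = _restricted(matrix, marker_set)
    X = sub.to_numpy(dtype=float).T  # samples x probes
    Z = hierarchy.linkage(X, method=method, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    cluster_of = {s: relabel[lab] for s, lab in zip(matrix.columns, raw)}
    means = {
        c: float(sub[[s for s, cc in cluster_of.items() if cc == c]].to_numpy().mean())
        for c in sorted(set(cluster_of.values()))
    }
    return ClusterAssignment(
        cluster_of=cluster_of,
        subgroup_of_cluster=None,
        linkage_method=method,
        distance_metric=metric,
        cluster_marker_mean=means,
    )


def assign_subgroup_labels(
    assignment: ClusterAssignment,
    matrix: pd.DataFrame,
    marker_set: MarkerSet,
) -> ClusterAssignment:
    """Label the two clusters: higher mean marker beta -> PFA, lower -> PFB."""
    clusters = sorted(set(assignment.cluster_of.values()))
    if len(clusters) != 2:
        raise ValidationError(f"expected exactly 2 clusters, found {len(clusters)}")
    sub = _restricted(matrix, marker_set)
    means = {}
    for c in clusters:
        samples = [s for s, cc in assignment.cluster_of.items() if cc == c]
        means[c] = float(sub[samples].to_numpy().mean())
    hi, lo = max(clusters, key=lambda c: means[c]), min(clusters, key=lambda c: means[c])
    if means[hi] == means[lo]:
        raise UnresolvedLabelError(
            f"both clusters have mean marker beta {means[hi]:.6f}; cannot orient PFA/PFB")
    return ClusterAssignment(
        cluster_of=dict(assignment.cluster_of),
        subgroup_of_cluster={hi: "PFA", lo: "PFB"},
        linkage_method=assignment.linkage_method,
        distance_metric=assignment.distance_metric,
        cluster_marker_mean=means,
    )
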
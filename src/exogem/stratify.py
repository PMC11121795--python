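"""Hierarchical clustering and group-contribution analysis.

Agglomerative clustering with Euclidean distance and complete linkage,
flat cuts at k clusters, row standardization for heatmap-style
displays, and per-cluster group contribution proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

__all__ = [
    "ClusterAssignment",
    "hierarchical_cluster",
    "row_standardize",
    "cluster_group_contributions",
    "export_heatmap_tsv",
]


@dataclass
class ClusterAssignment:
    leaf_order: np.ndarray  # permutation of item indices (dendrogram order)
    merge_tree: np.ndarray  # scipy linkage matrix
    labels: np.ndarray  # flat assignment at k clusters (1..k)
    k: int
    item_ids: list[str] = field(default_factory=list)
    axis: str = "rows"

    def members(self, cluster: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels == cluster)]

    def to_json(self, path: str) -> None:
        import json

        doc = {
            "axis": self.axis,
            "k": int(self.k),
            "leaf_order": [int(i) for i in self.leaf_order],
            "labels": [int(v) for v in self.labels],
            "item_ids": self.item_ids,
            "merge_tree": self.merge_tree.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def hierarchical_cluster(matrix, axis: str = "rows", k: int = 2) -> ClusterAssignment:
    """Complete-linkage Euclidean clustering with a flat cut at k."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index if axis == "rows" else matrix.columns)
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        ids = []
    if axis == "columns":
        data = data.T
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items on the clustered axis")
    if k > n:
        raise ValueError(f"k={k} exceeds item count {n}")
    if not ids:
        ids = [str(i) for i in range(n)]
    Z = linkage(data, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        leaf_order=np.asarray(leaves_list(Z)),
        merge_tree=Z,
        labels=np.asarray(labels),
        k=k,
        item_ids=ids,
        axis=axis,
    )


def row_standardize(matrix) -> tuple[pd.DataFrame, list]:
    """Z-score each row (mean 0, sd 1); constant rows become 0, flagged.

    Returns (standardized matrix, list of flagged row labels).
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix, float))
    values = df.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, ddof=0, keepdims=True)
    flagged_mask = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[flagged_mask, :] = 0.0
    flagged = [df.index[i] for i in np.flatnonzero(flagged_mask)]
    return pd.DataFrame(z, index=df.index, columns=df.columns), flagged


def cluster_group_contributions(
    assignment: ClusterAssignment,
    group_labels: dict[str, str] | list[str],
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster proportion of members from each group.

    ``groups`` fixes the group universe (defaults to all labels seen);
    proportions per cluster sum to 1.
    """
    if isinstance(group_labels, dict):
        try:
            labels = [group_labels[i] for i in assignment.item_ids]
        except KeyError as exc:
            raise ValueError(f"missing group label for item {exc.args[0]!r}") from exc
    else:
        labels = list(group_labels)
        if len(labels) != len(assignment.labels):
            raise ValueError("one group label per clustered item required")
    universe = groups or sorted(set(labels))
    unknown = set(labels) - set(universe)
    if unknown:
        raise ValueError(f"labels outside the group universe: {sorted(unknown)}")
    rows = {}
    for cl in sorted(set(assignment.labels.tolist())):
        members = [labels[i] for i in np.flatnonzero(assignment.labels == cl)]
        rows[cl] = {g: members.count(g) / len(members) for g in universe}
    return pd.DataFrame(rows).T[universe]


def export_heatmap_tsv(
    matrix: pd.DataFrame,
    row_assignment: ClusterAssignment | None,
    col_assignment: ClusterAssignment | None,
    path: str,
) -> pd.DataFrame:
    """Write the dendrogram-reordered matrix as TSV; returns it too."""
    out = matrix
    if row_assignment is not None:
        out = out.iloc[row_assignment.leaf_order, :]
    if col_assignment is not None:
        out = out.iloc[:, col_assignment.leaf_order]
    out.to_csv(path, sep="\t")
    return out
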
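"""Unsupervised structure on signature matrices.

Ward/Euclidean hierarchical clustering of genes or samples, k-way sample
partitions (the high/medium/low driver-expression split at k = 3), and
sample-correlation heatmap matrices.  Linkage and tree cutting are
delegated to :mod:`scipy.cluster.hierarchy`; this module fixes the
conventions (Ward heights as sqrt(2 x variance increase), partition
naming by mean driver reference) and wraps the results in audited types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .matrix_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTree",
    "Partition",
    "ward_linkage",
    "cut_tree",
    "log_ratio_profiles",
    "sample_correlation_matrix",
]


@dataclass
class LinkageTree:
    """An agglomerative merge sequence over n leaves (n - 1 merges).

    ``linkage`` is the scipy linkage matrix: each row
    (node_a, node_b, height, size) in merge order; nodes >= n refer to
    earlier merges.  Ward heights are monotone non-decreasing.
    """

    linkage: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have exactly n - 1 merges")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("Ward heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_members(self) -> list[frozenset[str]]:
        """Leaf-id membership of the cluster formed at each merge step."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([fid]) for i, fid in enumerate(self.leaf_ids)
        }
        out = []
        for step, (a, b, _h, _s) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            out.append(merged)
        return out

    def leaf_order(self) -> list[str]:
        """Reproducible dendrogram leaf ordering for heatmap export."""
        order = hierarchy.leaves_list(self.linkage.astype(float))
        return [self.leaf_ids[i] for i in order]


@dataclass
class Partition:
    """A k-way partition with clusters ranked by mean driver reference.

    Cluster indices run 1..k with 1 the highest mean driver reference;
    at k = 3 the names high/medium/low are attached.
    """

    labels: dict[str, int]
    k: int
    cluster_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        observed = set(self.labels.values())
        if observed != set(range(1, self.k + 1)):
            raise ValueError(f"expected exactly {self.k} non-empty clusters, got {sorted(observed)}")

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]


def ward_linkage(
    points: np.ndarray | ExpressionMatrix, leaf_ids: Sequence[str] | None = None
) -> LinkageTree:
    """Ward minimum-variance agglomeration with Euclidean distance.

    When given an :class:`ExpressionMatrix` the FEATURES (rows) are the
    items clustered; transpose beforehand (or pass ``m.values.T`` with
    sample ids) to cluster samples.  The merge height is the conventional
    sqrt(2 x increase in total within-cluster sum of squares), which for
    two singletons reduces to their Euclidean distance.
    """
    if isinstance(points, ExpressionMatrix):
        leaf_ids = points.feature_ids if leaf_ids is None else list(leaf_ids)
        x = points.values
    else:
        x = np.asarray(points, dtype=float)
        if x.ndim != 2:
            raise ValueError("points must be a 2-D items x dims array")
        leaf_ids = [str(i) for i in range(x.shape[0])] if leaf_ids is None else list(leaf_ids)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in clustering input")
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    return LinkageTree(z, list(leaf_ids))


def cut_tree(
    tree: LinkageTree,
    k: int,
    driver_reference: Sequence[float] | None = None,
) -> Partition:
    """The k clusters obtained by undoing the tree's last k - 1 merges.

    Clusters are ranked by the mean ``driver_reference`` value of their
    members (descending; ties broken by larger cluster size, then first
    leaf): cluster 1 is "high", cluster k is "low".  Without a reference,
    ranking falls back to first-leaf order.
    """
    n = tree.n_leaves
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}]")
    raw = hierarchy.cut_tree(tree.linkage.astype(float), n_clusters=k).ravel()
    ref = None
    if driver_reference is not None:
        ref = np.asarray(driver_reference, dtype=float)
        if ref.size != n:
            raise ValueError("driver_reference length must equal leaf count")

    keys = []
    for c in sorted(set(raw)):
        idx = np.where(raw == c)[0]
        mean_ref = float(ref[idx].mean()) if ref is not None else -float(idx[0])
        keys.append((c, mean_ref, len(idx), int(idx[0])))
    # descending mean reference, ties by size then first leaf
    keys.sort(key=lambda t: (-t[1], -t[2], t[3]))
    rank = {c: i + 1 for i, (c, *_rest) in enumerate(keys)}

    labels = {tree.leaf_ids[i]: rank[raw[i]] for i in range(n)}
    names = {}
    if k == 3 and ref is not None:
        names = {1: "high", 2: "medium", 3: "low"}
    return Partition(labels=labels, k=k, cluster_names=names)


def log_ratio_profiles(
    m: ExpressionMatrix, center: Literal["median", "mean"] = "median"
) -> ExpressionMatrix:
    """Gene-wise centered log profiles (log-ratio to each gene's typical sample).

    Subtracting the per-gene median (default) of log values is the log of
    the ratio to the gene's median sample.  Requires log-scale input;
    linear input must be log-transformed first.
    """
    if m.scale_tag != "log":
        raise ValueError(
            "log_ratio_profiles requires log-scale input; log-transform the matrix first"
        )
    values = m.values
    if center == "median":
        c = np.median(values, axis=1, keepdims=True)
    elif center == "mean":
        c = values.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown center {center!r}")
    return ExpressionMatrix.from_arrays(
        m.feature_ids, m.sample_ids, values - c, scale_tag="log", platform_tag=m.platform_tag
    )


def sample_correlation_matrix(
    m: ExpressionMatrix, method: Literal["pearson", "spearman"] = "pearson"
) -> np.ndarray:
    """Symmetric sample x sample correlation matrix with exact unit diagonal.

    Entry (i, j) correlates samples i and j across all features.
    Constant sample vectors produce NaN rows/columns (flagged in the log)
    rather than an error.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    values = m.values
    if method == "spearman":
        values = np.apply_along_axis(stats.rankdata, 0, values)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xc = values - values.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    degenerate = norms == 0.0
    if degenerate.any():
        logger.warning(
            "sample_correlation_matrix: %d constant sample(s) flagged as NaN",
            int(degenerate.sum()),
        )
    safe = np.where(degenerate, 1.0, norms)
    c = (xc.T @ xc) / np.outer(safe, safe)
    c = np.clip(c, -1.0, 1.0)
    c[degenerate, :] = np.nan
    c[:, degenerate] = np.nan
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, np.where(degenerate, np.nan, 1.0))
    return c
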
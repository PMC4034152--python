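"""Hierarchical cluster analysis of preprocessed spectra.

Ward's minimum-variance linkage on Euclidean distances between the
normalized second-derivative feature vectors, with merge heights reported
in distance units (the ward.D2 convention: height² equals twice the
increase in total within-cluster sum of squares).  "Heterogeneity" — the
quantity the dendrogram displays — is the merge height at which a cluster
forms; a low subtree height relative to its parent species cluster marks a
homogeneous subgroup.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .preprocess import FeatureVector

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "ClusterReport",
    "distance_matrix",
    "ward_linkage",
    "cut_tree",
    "species_report",
    "heterogeneity_ratio",
    "export_newick",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class LinkageTree:
    """Ward dendrogram: scipy linkage matrix plus the leaf order."""

    Z: np.ndarray  # scipy (n-1, 4) linkage matrix
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.leaf_ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def node_leafsets(self) -> list[frozenset[str]]:
        """Leaf-id set of every node (0..n-1 leaves, then merges in order)."""
        n = self.n_leaves
        sets: list[frozenset[str]] = [frozenset([lid]) for lid in self.leaf_ids]
        for a, b, _, _ in self.Z:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets


@dataclass
class ClusterReport:
    k: int
    assignments: dict[str, int]
    cluster_label: dict[int, str]
    n_misassigned: int
    accuracy: float
    per_cluster_heterogeneity: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "accuracy": self.accuracy,
            "n_misassigned": self.n_misassigned,
            "cluster_label": {str(c): s for c, s in self.cluster_label.items()},
            "per_cluster_heterogeneity": {
                str(c): h for c, h in self.per_cluster_heterogeneity.items()
            },
            "assignments": dict(self.assignments),
        }


def distance_matrix(features: Sequence[FeatureVector]) -> DistanceMatrix:
    """Pairwise Euclidean distances between feature vectors."""
    if not features:
        raise ValueError("no feature vectors")
    support = features[0].support
    for f in features[1:]:
        if f.support.shape != support.shape or not np.array_equal(f.support, support):
            raise ValueError(
                f"feature support of {f.sample_id!r} differs from "
                f"{features[0].sample_id!r}"
            )
    X = np.vstack([f.values for f in features])
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(ids=[f.sample_id for f in features], d=d)


def ward_linkage(dm: DistanceMatrix, variant: str = "ward_d2") -> LinkageTree:
    """Agglomerative Ward linkage on Euclidean distances.

    ``ward_d2`` (default) reports heights in distance units; ``ward_d``
    runs the same Lance–Williams recursion on unsquared distances, for
    sensitivity checks only.
    """
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    cond = dm.condensed
    if not np.all(np.isfinite(cond)):
        raise ValueError("distance matrix contains non-finite values")
    if variant == "ward_d2":
        Z = hierarchy.linkage(cond, method="ward")
    elif variant == "ward_d":
        # Lance–Williams recursion on the raw (unsquared) distances: run the
        # D2 algorithm on sqrt(d) and square the resulting heights.
        Z = hierarchy.linkage(np.sqrt(cond), method="ward").copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward variant {variant!r}")
    return LinkageTree(Z=Z, leaf_ids=list(dm.ids))


def cut_tree(t: LinkageTree, k: int) -> dict[str, int]:
    """Partition into k clusters by undoing the last k − 1 merges.

    Cluster indices are 0..k−1 in order of first appearance along the leaf
    list.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    labels = hierarchy.cut_tree(t.Z, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for lid, lab in zip(t.leaf_ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[lid] = remap[lab]
    return out


def _internal_merge_heights(t: LinkageTree, assignments: dict[str, int]) -> dict[int, float]:
    """Height at which each cluster of the partition last merges internally."""
    heights = {c: 0.0 for c in set(assignments.values())}
    sets = t.node_leafsets()
    for (a, b, h, _), node_set in zip(t.Z, sets[t.n_leaves:]):
        clusters = {assignments[lid] for lid in node_set}
        if len(clusters) == 1:
            c = clusters.pop()
            heights[c] = max(heights[c], float(h))
    return heights


def species_report(
    t: LinkageTree, truth: Mapping[str, str], k: int
) -> ClusterReport:
    """Cut at k, label clusters by majority species, score misassignments."""
    missing = [lid for lid in t.leaf_ids if lid not in truth]
    if missing:
        raise ValueError(f"truth labels missing for {missing[:5]}")
    assignments = cut_tree(t, k)
    cluster_label: dict[int, str] = {}
    for c in sorted(set(assignments.values())):
        counts = Counter(truth[lid] for lid, cc in assignments.items() if cc == c)
        top = max(counts.values())
        winners = sorted(s for s, m in counts.items() if m == top)
        if len(winners) > 1:
            logger.warning(
                "cluster %d majority tie between %s; labelling %s",
                c, winners, winners[0],
            )
        cluster_label[c] = winners[0]
    n_mis = sum(
        1 for lid, c in assignments.items() if truth[lid] != cluster_label[c]
    )
    n = t.n_leaves
    return ClusterReport(
        k=k,
        assignments=assignments,
        cluster_label=cluster_label,
        n_misassigned=n_mis,
        accuracy=1.0 - n_mis / n,
        per_cluster_heterogeneity=_internal_merge_heights(t, assignments),
    )


def _subtree_height(t: LinkageTree, group: frozenset[str]) -> float:
    sets = t.node_leafsets()
    heights = [0.0] * t.n_leaves + [float(h) for h in t.Z[:, 2]]
    for node_set, h in zip(sets, heights):
        if node_set == group:
            return h
    unknown = sorted(group - set(t.leaf_ids))
    if unknown:
        raise ValueError(f"leaves not in tree: {unknown}")
    raise ValueError(
        f"group of {len(group)} leaves is not a connected subtree "
        f"(e.g. {sorted(group)[:5]})"
    )


def heterogeneity_ratio(
    t: LinkageTree, group_a: Sequence[str], group_b: Sequence[str]
) -> float:
    """Ratio of subtree heterogeneities (root merge heights) a / b.

    Each group must be exactly the leaf set of some node of the tree.
    """
    a, b = frozenset(group_a), frozenset(group_b)
    ha = _subtree_height(t, a)
    hb = _subtree_height(t, b)
    if hb == 0.0:
        if a == b:
            return 1.0
        raise ValueError("group_b is a singleton (zero heterogeneity)")
    return ha / hb


def export_newick(t: LinkageTree, path: str | Path | None = None) -> str:
    """Serialize the dendrogram as Newick with ultrametric branch lengths.

    Node depth is merge height / 2, so a two-leaf tree of merge height h
    becomes ``(a:h/2,b:h/2);`` and every leaf sits at the same total depth.
    Returns the Newick string; writes it to ``path`` when given.
    """
    n = t.n_leaves
    heights = [0.0] * n + [float(h) for h in t.Z[:, 2]]
    children = {
        n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(t.Z)
    }

    def label(leaf: int) -> str:
        raw = t.leaf_ids[leaf]
        safe = raw.replace(" ", "_")
        if any(ch in safe for ch in "():,;'\""):
            return "'" + raw.replace("'", "''") + "'"
        return safe

    root = n + len(t.Z) - 1 if len(t.Z) else 0
    # Iterative post-order build (no recursion limit worries on deep trees).
    parts: dict[int, str] = {}
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if node < n:
            parts[node] = label(node)
            continue
        if not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in children[node])
            continue
        a, b = children[node]
        pieces = []
        for c in (a, b):
            branch = (heights[node] - heights[c]) / 2.0
            pieces.append(f"{parts.pop(c)}:{branch:.12g}")
        parts[node] = "(" + ",".join(pieces) + ")"
    newick = parts[root] + ";"
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
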
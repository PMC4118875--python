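"""Dendrogram-based outlier screening and class-similarity trees.

Replicate LIBS shots from one homogeneous pellet should cluster tightly;
a spectrum hit by a surface contaminant, a misfire or a detector glitch
appears as an *isolated branch* of the agglomerative dendrogram — a
singleton (or tiny cluster) that only joins the remainder of its class at
an anomalously large merge height. The default rule flags branches of
size at most ``max_branch_size`` whose merge into the rest happens above
``height_factor`` times the median merge height of the tree.

The same machinery, applied to per-class mean spectra, yields the
class-similarity dendrogram that shows which formulations resemble each
other spectrally.

Clustering is delegated to :mod:`scipy.cluster.hierarchy`; the default
Ward linkage on Euclidean distances produces monotone merge heights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .errors import ClassSizeError, DimensionError
from .spectra import SpectraSet

__all__ = [
    "DendrogramTree",
    "OutlierRule",
    "hierarchical_cluster",
    "detect_outliers",
    "detect_outliers_by_class",
    "class_mean_spectra",
    "class_similarity_dendrogram",
    "tree_to_newick",
    "tree_to_json",
]


@dataclass(frozen=True)
class DendrogramTree:
    """An agglomerative tree: scipy-format merge list plus leaf identities.

    ``merges`` has one row per merge — ``(node_a, node_b, height, size)``
    with nodes below ``n`` being leaves and node ``n + j`` the cluster
    created by merge ``j``. ``leaf_ids`` maps leaf positions to spectrum
    row indices or class names.
    """

    merges: np.ndarray
    leaf_ids: tuple
    metric: str = "euclidean"
    linkage: str = "ward"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass(frozen=True)
class OutlierRule:
    """Operationalization of "isolated branch".

    A branch is flagged when its size is at most ``max_branch_size`` and
    it joins the rest of the tree at a height exceeding ``height_factor``
    times the median merge height.
    """

    height_factor: float = 3.0
    max_branch_size: int = 2

    def __post_init__(self):
        if self.height_factor <= 0:
            raise ValueError("height_factor must be > 0")
        if self.max_branch_size < 1:
            raise ValueError("max_branch_size must be >= 1")


def hierarchical_cluster(
    spectra: SpectraSet, metric: str = "euclidean", linkage: str = "ward"
) -> DendrogramTree:
    """Agglomerative clustering of the rows of a SpectraSet."""
    n = spectra.n_spectra
    if n < 2:
        raise DimensionError("clustering needs at least two spectra")
    X = spectra.valid_matrix()
    if X.shape[1] < 1:
        raise DimensionError("no valid channels")
    merges = hierarchy.linkage(X, method=linkage, metric=metric)
    return DendrogramTree(merges, tuple(range(n)), metric, linkage)


def _cluster_leaves(merges: np.ndarray, n: int) -> list[list[int]]:
    """Leaf sets of every internal node, indexed by merge number."""
    leaves: list[list[int]] = []
    for a, b, _, _ in merges:
        members: list[int] = []
        for node in (int(a), int(b)):
            members.extend([node] if node < n else leaves[node - n])
        leaves.append(members)
    return leaves


def detect_outliers(tree: DendrogramTree, rule: OutlierRule = OutlierRule()) -> list:
    """Leaf ids on isolated branches, per the rule. Deterministic; may be empty."""
    n = tree.n_leaves
    merges = tree.merges
    cutoff = rule.height_factor * float(np.median(merges[:, 2]))
    leaves = _cluster_leaves(merges, n)
    flagged: set[int] = set()
    for j, (a, b, height, _) in enumerate(merges):
        if height <= cutoff:
            continue
        for node in (int(a), int(b)):
            members = [node] if node < n else leaves[node - n]
            if len(members) <= rule.max_branch_size:
                flagged.update(members)
    return sorted(tree.leaf_ids[i] for i in flagged)


def detect_outliers_by_class(
    spectra: SpectraSet,
    rule: OutlierRule = OutlierRule(),
    metric: str = "euclidean",
    linkage: str = "ward",
) -> np.ndarray:
    """Run isolated-branch detection within each class; global row indices.

    Screening per formulation matches how the class means are later
    computed; classes with fewer than 3 rows are left unscreened.
    """
    flagged: list[int] = []
    for name in spectra.classes:
        idx = spectra.class_indices(name)
        if idx.size < 3:
            continue
        tree = hierarchical_cluster(spectra.select(idx), metric, linkage)
        flagged.extend(int(idx[i]) for i in detect_outliers(tree, rule))
    return np.array(sorted(flagged), dtype=int)


def class_mean_spectra(spectra: SpectraSet, exclude=()) -> SpectraSet:
    """Per-class arithmetic mean spectra, after excluding flagged rows."""
    excluded = {int(i) for i in np.asarray(exclude, dtype=int).ravel()}
    rows, labels = [], []
    for name in spectra.classes:
        idx = [int(i) for i in spectra.class_indices(name) if int(i) not in excluded]
        if not idx:
            raise ClassSizeError(
                f"class {name!r} has no rows left after exclusion", class_name=name
            )
        rows.append(spectra.intensities[idx].mean(axis=0))
        labels.append(name)
    return SpectraSet(
        spectra.wavelengths.copy(),
        np.vstack(rows),
        labels,
        spectra.valid_mask.copy(),
        provenance=[f"mean({l})" for l in labels],
    )


def class_similarity_dendrogram(
    mean_set: SpectraSet, metric: str = "euclidean", linkage: str = "ward"
) -> DendrogramTree:
    """Dendrogram over class-mean spectra, leaves labelled by class name."""
    if mean_set.n_spectra < 2:
        raise DimensionError("need at least two classes")
    tree = hierarchical_cluster(mean_set, metric, linkage)
    return DendrogramTree(tree.merges, tuple(mean_set.labels), metric, linkage)


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------


def tree_to_json(tree: DendrogramTree) -> str:
    """Merge list + leaf ids as a JSON document."""
    return json.dumps(
        {
            "leaf_ids": list(tree.leaf_ids),
            "merges": [
                {"node_a": int(a), "node_b": int(b), "height": float(h), "size": int(s)}
                for a, b, h, s in tree.merges
            ],
            "metric": tree.metric,
            "linkage": tree.linkage,
        },
        indent=2,
    )


def tree_to_newick(tree: DendrogramTree) -> str:
    """Newick serialization with branch lengths from merge heights."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for j, (_, _, h, _) in enumerate(tree.merges):
        heights[n + j] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            name = str(tree.leaf_ids[node]).replace(" ", "_")
            return f"{name}:{length:.6g}"
        a, b, h, _ = tree.merges[node - n]
        inner = ",".join(render(int(c), float(h)) for c in (a, b))
        return f"({inner}):{length:.6g}"

    a, b, h, _ = tree.merges[-1]
    inner = ",".join(render(int(c), float(h)) for c in (a, b))
    return f"({inner});"
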
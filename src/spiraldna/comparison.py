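"""Pairwise descriptor distances, matrix normalization, clustering, tree export.

The similarity distance between two species is the plain Euclidean distance
between their 4-D descriptors; small values mean evolutionary closeness.
Matrices live in `skbio.DistanceMatrix` (labels + symmetry + zero diagonal
enforced by the container). Agglomerative clustering (UPGMA by default, the
convention in this comparison literature) turns a matrix into an ultrametric
tree exported as Newick; matrices round-trip through a square PHYLIP format.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage, to_tree
from skbio import DistanceMatrix, TreeNode

from .descriptor import DescriptorVector

LINKAGES = ("average", "single", "complete")


def _as_vec(v) -> np.ndarray:
    if isinstance(v, DescriptorVector):
        return v.as_array()
    return np.asarray(v, dtype=float)


def euclidean_distance(v1, v2) -> float:
    """Euclidean similarity distance between two 4-D descriptors.

    Accepts `DescriptorVector` or plain arrays. Warns when the two vectors
    were computed under different parameter fingerprints — such distances mix
    geometries and are not meaningful.
    """
    if (
        isinstance(v1, DescriptorVector)
        and isinstance(v2, DescriptorVector)
        and v1.params_fingerprint != v2.params_fingerprint
    ):
        warnings.warn(
            f"descriptors {v1.label!r} and {v2.label!r} were computed under "
            "different parameters; their distance is not comparable",
            stacklevel=2,
        )
    return float(np.linalg.norm(_as_vec(v1) - _as_vec(v2)))


def distance_matrix(vectors: Sequence[DescriptorVector]) -> DistanceMatrix:
    """All-pairs similarity distances over labeled descriptors."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 descriptor vectors")
    labels = [v.label for v in vectors]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate descriptor labels")
    fps = {v.params_fingerprint for v in vectors}
    if len(fps) > 1:
        warnings.warn(
            "descriptor set mixes parameter fingerprints; distances are not comparable",
            stacklevel=2,
        )
    arr = np.array([v.as_array() for v in vectors])
    diff = arr[:, None, :] - arr[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=labels)


def matrix_from_arrays(values: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    """Wrap a precomputed square matrix with labels (validates symmetry)."""
    return DistanceMatrix(np.asarray(values, dtype=float), ids=list(labels))


def normalize_matrix(matrix: DistanceMatrix, ref_pair: tuple[str, str]) -> DistanceMatrix:
    """Scale the whole matrix so the reference pair's distance is exactly 1.

    Used to put distance matrices from different descriptor methods on a
    common scale for side-by-side reporting. Idempotent.
    """
    a, b = ref_pair
    ref = matrix[a, b]
    if ref == 0:
        raise ValueError(f"reference pair {ref_pair} has zero distance")
    return DistanceMatrix(matrix.data / ref, ids=matrix.ids)


def cluster(matrix: DistanceMatrix, linkage: str = "average") -> TreeNode:
    """Agglomerative hierarchical clustering of a distance matrix.

    ``average`` linkage is UPGMA. The returned tree is ultrametric: every
    merge sits at half the inter-cluster distance, so each leaf is at depth
    (root height)/2. Ties are resolved by the (deterministic) order of
    scipy's agglomeration for a fixed input.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    Z = _scipy_linkage(matrix.condensed_form(), method=linkage)
    return _linkage_to_treenode(Z, list(matrix.ids))


def _linkage_to_treenode(Z: np.ndarray, ids: list[str]) -> TreeNode:
    """Scipy linkage matrix -> skbio TreeNode with ultrametric branch lengths."""
    root = to_tree(Z)

    def build(node):
        if node.is_leaf():
            tn = TreeNode(name=ids[node.id])
            height = 0.0
        else:
            left, lh = build(node.left)
            right, rh = build(node.right)
            height = node.dist / 2.0
            left.length = height - lh
            right.length = height - rh
            tn = TreeNode(children=[left, right])
        return tn, height

    tree, _ = build(root)
    return tree


def is_cherry(tree: TreeNode, a: str, b: str) -> bool:
    """True when leaves a and b are siblings (their parent has exactly them)."""
    tip = {t.name: t for t in tree.tips()}
    parent = tip[a].parent
    names = sorted(c.name for c in parent.children if c.is_tip())
    return len(parent.children) == 2 and names == sorted([a, b])


def clade_names(tree: TreeNode) -> list[frozenset]:
    """Leaf-name sets of every internal node (the tree's clades)."""
    out = []
    for node in tree.non_tips(include_self=True):
        out.append(frozenset(t.name for t in node.tips()))
    return out


def write_tree(tree: TreeNode, path: str | Path) -> None:
    """Write a tree to Newick with branch lengths."""
    tree.write(str(Path(path)), format="newick")


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(Path(path)), format="newick")


def write_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix (full precision, relaxed names)."""
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[0]}\n")
        for label, row in zip(matrix.ids, matrix.data):
            values = " ".join(format(v, ".17g") for v in row)
            fh.write(f"{label}  {values}\n")


def read_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by `write_matrix`."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln for ln in tokens if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    if len(labels) != n:
        raise ValueError(f"expected {n} taxa, found {len(labels)}")
    return DistanceMatrix(np.array(rows), ids=labels)


def query_report(matrix: DistanceMatrix, query: str) -> "pd.DataFrame":
    """One matrix row as a tidy query-vs-all table, 4-decimal distances."""
    import pandas as pd

    others = [i for i in matrix.ids if i != query]
    return pd.DataFrame(
        {"species": others, "distance": [round(matrix[query, o], 4) for o in others]}
    )
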
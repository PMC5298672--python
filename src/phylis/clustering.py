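"""Distance matrices and dendrograms over sets of preprocessed spectra.

Spectra are compared by Euclidean distance over their 1000 positions and
clustered agglomeratively (average linkage by default).  With only a couple
of replicates per crop a dendrogram is the appropriate exploratory summary of
whether within-crop spectral variation is smaller than between-crop
variation; :func:`cluster_purity` quantifies that visually-assessed property
as the fraction of classes whose replicates form a pure subtree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .errors import DegenerateInput

LINKAGES = ("average", "single", "complete")


def spectral_distance(a, b) -> float:
    """Euclidean distance between two spectra: sqrt(Σ_p (a_p − b_p)²)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Euclidean distance matrix with sample labels."""

    d: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_spectra(cls, spectra, labels) -> "DistanceMatrix":
        """Pairwise Euclidean distances between rows of an (n, p) array."""
        X = np.asarray(spectra, dtype=float)
        return cls(d=squareform(pdist(X, metric="euclidean")),
                   labels=[str(x) for x in labels])

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) with leaf labels."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]
    linkage_method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        """Merge heights, in merge order (non-decreasing for average/complete)."""
        return self.merges[:, 2]

    def to_tree(self) -> TreeNode:
        """Rooted tree with branch lengths equal to merge-height differences."""
        return TreeNode.from_linkage_matrix(self.merges, self.labels)

    def to_newick(self, path=None) -> str:
        tree = self.to_tree()
        if path is not None:
            tree.write(str(path), format="newick")
        return str(tree)

    def leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label set under every internal node."""
        root = to_tree(self.merges)
        sets: list[frozenset[str]] = []

        def collect(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([self.labels[node.id]])
            s = collect(node.left) | collect(node.right)
            sets.append(s)
            return s

        collect(root)
        return sets


def build_dendrogram(dm: DistanceMatrix, linkage_method: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Supports average (UPGMA, the default), single and complete linkage.
    Deterministic for a fixed matrix.
    """
    if dm.n < 2:
        raise DegenerateInput("need at least 2 samples to build a dendrogram")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    Z = linkage(dm.condensed(), method=linkage_method)
    return Dendrogram(merges=Z, labels=list(dm.labels), linkage_method=linkage_method)


def cluster_purity(dend: Dendrogram, class_of: dict[str, str] | list[str]) -> float:
    """Fraction of classes whose members form a pure subtree.

    A class is *pure* if the set of its leaves appears exactly as the leaf
    set of some node of the dendrogram (singleton classes are trivially
    pure).  Purity 1.0 means every class's replicates merged together before
    joining any other class.
    """
    if isinstance(class_of, dict):
        mapping = class_of
    else:
        mapping = dict(zip(dend.labels, class_of))
    classes: dict[str, set[str]] = {}
    for leaf, cls in mapping.items():
        classes.setdefault(str(cls), set()).add(leaf)
    node_sets = set(dend.leaf_sets())
    pure = 0
    for members in classes.values():
        if len(members) == 1 or frozenset(members) in node_sets:
            pure += 1
    return pure / len(classes)
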
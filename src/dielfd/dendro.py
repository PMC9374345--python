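"""Gower dissimilarity, UPGMA functional dendrograms, and dendrogram FD.

Functional diversity (FD) of a species set is measured as the total branch
length of an ultrametric UPGMA dendrogram built from Gower trait
dissimilarities: merge heights follow the hclust convention (a pair joining
at average dissimilarity h sits at height h; leaves at height 0), each branch
contributes (parent height - child height), and a single leaf has FD 0.

One global dendrogram is built over all species; the FD of any subset (a diel
niche within a map pixel, the survivors of an extinction scenario) comes from
pruning, which preserves the cophenetic distances among kept leaves exactly.
The cophenetic distance between two leaves is the height at which they first
join.  Congruence diagnostics quantify how faithfully the dendrogram
preserves the original Gower distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .traits import TransformedTraits, gower_distances

__all__ = [
    "DistanceMatrix",
    "FunctionalDendrogram",
    "gower_matrix",
    "upgma",
    "tree_height",
    "prune",
    "cophenetic_matrix",
    "congruence",
    "fd_of_subset",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with species labels."""

    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        V = np.asarray(self.values, dtype=float)
        if V.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(V).any():
            raise ValueError("distance matrix has a nonzero diagonal")
        self.values = (V + V.T) / 2.0

    def submatrix(self, ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(np.asarray(list(ids)), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(), df.to_numpy(float))


def gower_matrix(
    traits: TransformedTraits, weights: np.ndarray | None = None
) -> DistanceMatrix:
    """Equal-weight Gower distance over the five (transformed) traits.

    The ordinal foraging stratum is treated as interval on its 1-4 scale;
    range normalization uses the observed per-trait range, making the result
    invariant to affine rescaling of any single trait column.
    """
    D = gower_distances(traits.matrix(), weights)
    return DistanceMatrix(traits.species_ids, D)


@dataclass
class FunctionalDendrogram:
    """UPGMA merge tree in scipy linkage form.

    ``merges`` has one row per internal node: (left, right, height, size)
    where indices < n refer to leaves in ``ids`` order and n + k refers to the
    k-th merge.  Heights are the hclust-convention average dissimilarities,
    non-decreasing from first to last merge.
    """

    ids: np.ndarray
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.merges = np.asarray(self.merges, dtype=float)

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def node_heights(self) -> np.ndarray:
        """Height of every node (leaves first, then merges)."""
        n = self.n_leaves
        h = np.zeros(n + len(self.merges))
        h[n:] = self.merges[:, 2]
        return h

    def to_newick(self) -> str:
        """Newick serialization with hclust-height branch lengths."""
        n = self.n_leaves
        heights = self.node_heights()

        def rec(node: int) -> str:
            if node < n:
                return str(self.ids[node])
            left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            h = heights[node]
            return (
                f"({rec(left)}:{h - heights[left]:.10g},"
                f"{rec(right)}:{h - heights[right]:.10g})"
            )

        if n == 1:
            return f"{self.ids[0]};"
        return rec(n + len(self.merges) - 1) + ";"


def upgma(d: DistanceMatrix) -> FunctionalDendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix."""
    if len(d.ids) < 2:
        raise ValueError("UPGMA needs at least 2 species")
    Z = linkage(d.condensed(), method="average")
    return FunctionalDendrogram(d.ids, Z)


def tree_height(t: FunctionalDendrogram) -> float:
    """Total branch length (FD) of the dendrogram.

    FD = sum over branches of (parent height - child height); equivalently
    each merge at height h with children at heights hl, hr contributes
    2h - hl - hr.  A single leaf has FD 0.
    """
    if t.n_leaves < 2:
        return 0.0
    heights = t.node_heights()
    n = t.n_leaves
    total = 0.0
    for k, (left, right, h, _) in enumerate(t.merges):
        total += 2.0 * h - heights[int(left)] - heights[int(right)]
    return float(total)


def cophenetic_matrix(t: FunctionalDendrogram) -> DistanceMatrix:
    """Cophenetic distances: the merge height at which two leaves first join."""
    if t.n_leaves < 2:
        return DistanceMatrix(t.ids, np.zeros((t.n_leaves, t.n_leaves)))
    c = cophenet(t.merges)
    return DistanceMatrix(t.ids, squareform(c, checks=False))


def prune(t: FunctionalDendrogram, keep) -> FunctionalDendrogram:
    """Restrict the dendrogram to a leaf subset.

    Walks the original merge list, dropping leaves outside ``keep`` and
    collapsing internal nodes left with a single child, so merge heights —
    and hence the cophenetic distances among kept leaves — are preserved
    bit-exactly.
    """
    leaf_set = set(t.ids.tolist())
    kept_set = {s for s in keep if s in leaf_set}
    if not kept_set:
        raise ValueError("keep set shares no species with the dendrogram")
    if len(kept_set) == len(t.ids):
        return FunctionalDendrogram(t.ids.copy(), t.merges.copy())

    kept_mask = np.array([s in kept_set for s in t.ids])
    new_ids = t.ids[kept_mask]
    if len(new_ids) == 1:
        return FunctionalDendrogram(new_ids, np.empty((0, 4)))

    n = t.n_leaves
    # rep[old node] -> (new cluster id, size) for the part of the node that
    # survives pruning, or None if nothing beneath it is kept
    rep: list[tuple[int, int] | None] = [None] * (n + len(t.merges))
    new_pos = {s: i for i, s in enumerate(new_ids)}
    for i, s in enumerate(t.ids):
        if s in kept_set:
            rep[i] = (new_pos[s], 1)
    merges = []
    nxt = len(new_ids)
    for k, (left, right, h, _) in enumerate(t.merges):
        a, b = rep[int(left)], rep[int(right)]
        if a is None:
            rep[n + k] = b
        elif b is None:
            rep[n + k] = a
        else:
            size = a[1] + b[1]
            merges.append([a[0], b[0], h, size])
            rep[n + k] = (nxt, size)
            nxt += 1
    return FunctionalDendrogram(new_ids, np.array(merges, dtype=float))


def fd_of_subset(coph: DistanceMatrix, ids) -> float:
    """FD of a leaf subset straight from a precomputed cophenetic matrix.

    Fast path for per-pixel FD: avoids rebuilding the global tree.  Subsets
    of size 0 or 1 have FD 0 by definition.
    """
    ids = list(ids)
    if len(ids) < 2:
        return 0.0
    sub = coph.submatrix(ids)
    return tree_height(upgma(sub))


def congruence(d: DistanceMatrix, t: FunctionalDendrogram) -> dict[str, float]:
    """Agreement between Gower and cophenetic distances.

    Computed over the strict upper triangle: mean absolute deviation, mean
    squared deviation, and the Pearson correlation.  A dendrogram built from
    an already-ultrametric matrix reproduces it exactly (deviations 0,
    correlation 1).
    """
    if set(d.ids.tolist()) != set(t.ids.tolist()):
        raise ValueError("distance matrix and dendrogram cover different species")
    coph = cophenetic_matrix(t).submatrix(d.ids.tolist())
    iu = np.triu_indices(len(d.ids), k=1)
    a = d.values[iu]
    b = coph.values[iu]
    dev = b - a
    return {
        "mean_absolute_deviation": float(np.abs(dev).mean()),
        "mean_squared_deviation": float((dev**2).mean()),
        "pearson_correlation": float(np.corrcoef(a, b)[0, 1]),
    }
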
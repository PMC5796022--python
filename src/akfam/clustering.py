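"""Two-way UPGMA hierarchical clustering of a percent-identity matrix.

Rows are clustered on plain Euclidean distance between raw identity rows;
columns on distances between the columns of the row-reordered data. Z-score
transformation (row mean 0, sample SD 1) is applied only to the exported
visualization matrix, never to the data being clustered (selectable).

UPGMA is implemented directly rather than through a library linkage so that
the contract is explicit: inter-cluster distance is the unweighted
arithmetic mean over all cross pairs, merge height is half the merge
distance (so leaf-to-root path length equals half the cophenetic distance,
the ultrametric convention), and ties are broken by the lexicographically
smallest pair of cluster labels, a cluster's label being its smallest leaf
id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_formats import IdentityMatrix


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: node indices (leaves are 0..n-1, internal
    nodes n, n+1, ... in merge order) and the ultrametric height."""

    a: int
    b: int
    height: float


@dataclass
class MergeTree:
    """A rooted ultrametric dendrogram as an ordered list of merges."""

    leaf_ids: list[str]
    merges: list[Merge] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing (ultrametricity)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + k: (m.a, m.b) for k, m in enumerate(self.merges)}

    def _heights(self) -> dict[int, float]:
        n = self.n_leaves
        h = {i: 0.0 for i in range(n)}
        for k, m in enumerate(self.merges):
            h[n + k] = m.height
        return h

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the dendrogram."""
        if not self.merges:
            return list(self.leaf_ids)
        children = self._children()
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                stack.extend((b, a))  # a traversed first
        return [self.leaf_ids[i] for i in order]

    def cophenetic(self) -> np.ndarray:
        """n x n matrix of cophenetic distances (2 x merge height of the
        lowest common ancestor)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for k, m in enumerate(self.merges):
            for i in members[m.a]:
                for j in members[m.b]:
                    out[i, j] = out[j, i] = 2.0 * m.height
            members[n + k] = members.pop(m.a) + members.pop(m.b)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths (height differences)."""
        children = self._children()
        heights = self._heights()

        def fmt(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < self.n_leaves:
                return f"{self.leaf_ids[node]}:{bl:.6g}"
            a, b = children[node]
            h = heights[node]
            return f"({fmt(a, h)},{fmt(b, h)}):{bl:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        if not self.merges:
            return f"{self.leaf_ids[0]};"
        a, b = children[root]
        h = heights[root]
        return f"({fmt(a, h)},{fmt(b, h)});"


def upgma_linkage(d: np.ndarray, ids: list[str] | None = None) -> MergeTree:
    """UPGMA agglomeration of a square distance matrix.

    Raises on asymmetric, negative or nonzero-diagonal input."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if d.min() < 0:
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal must be zero")
    ids = ids if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length does not match matrix")

    # active clusters: node -> (label, size); label = smallest leaf id
    label = {i: ids[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    merges: list[Merge] = []
    next_node = n
    while len(active) > 1:
        best_key = min(
            dist,
            key=lambda k: (dist[k], tuple(sorted(label[x] for x in k))),
        )
        dmin = dist[best_key]
        i, j = sorted(best_key, key=lambda x: label[x])
        merges.append(Merge(i, j, dmin / 2.0))
        # unweighted arithmetic mean over all cross pairs
        for k in active - {i, j}:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_node, k))] = (size[i] * dik + size[j] * djk) / (
                size[i] + size[j]
            )
        del dist[best_key]
        active -= {i, j}
        label[next_node] = min(label[i], label[j])
        size[next_node] = size[i] + size[j]
        active.add(next_node)
        next_node += 1
    return MergeTree(leaf_ids=list(ids), merges=merges)


def zscore_rows(values: np.ndarray) -> np.ndarray:
    """Standardize each row to mean 0 and sample (n-1) standard deviation 1.

    Constant rows cannot be standardized; they map to all-zeros with a
    warning."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) mapped to zeros in z-scoring")
    safe = np.where(sd == 0, 1.0, sd)
    out = (x - mu) / safe
    out[constant, :] = 0.0
    return out


@dataclass
class ClusterResult:
    row_tree: MergeTree
    col_tree: MergeTree
    reordered: "pd.DataFrame"  # identity values, rows/columns in dendrogram order
    zscored: "pd.DataFrame"  # same layout, rows z-score transformed


def cluster_identity_matrix(m: IdentityMatrix, on: str = "raw") -> ClusterResult:
    """Two-way UPGMA clustering of an identity matrix.

    Rows first (Euclidean distance between raw identity rows), then columns
    of the row-reordered data; the exported visualization matrix is the
    doubly reordered matrix with z-scored rows. ``on='zscore'`` clusters the
    z-scored rows instead of raw identities."""
    if m.n < 2:
        raise ValueError("need at least two sequences to cluster")
    X = m.values if on == "raw" else zscore_rows(m.values)
    row_tree = upgma_linkage(squareform(pdist(X, metric="euclidean")), list(m.ids))
    row_order = row_tree.leaf_order()
    ridx = [m.ids.index(i) for i in row_order]
    Xr = X[ridx, :]
    col_tree = upgma_linkage(squareform(pdist(Xr.T, metric="euclidean")), list(m.ids))
    col_order = col_tree.leaf_order()
    cidx = [m.ids.index(i) for i in col_order]
    reordered_values = m.values[np.ix_(ridx, cidx)]
    reordered = pd.DataFrame(reordered_values, index=row_order, columns=col_order)
    zscored = pd.DataFrame(
        zscore_rows(reordered_values), index=row_order, columns=col_order
    )
    return ClusterResult(row_tree, col_tree, reordered, zscored)
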
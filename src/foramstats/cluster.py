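"""Agglomerative hierarchical clustering of samples under Ward's criterion.

Ward linkage merges, at each step, the pair of clusters whose fusion least
increases the total within-cluster sum of squares.  The merge sequence is
computed with the Lance-Williams recurrence; two conventions are offered:

* ``"D2"`` (default): the recurrence runs on squared distances and reported
  merge heights are square-rooted back to original distance units.  This is
  the appropriate convention when the input distances are Euclidean-embeddable
  (chord / Hellinger distances are).
* ``"D"``: the recurrence runs on the distances as given.

Tie-breaking among equal-cost merges is deterministic: the candidate pair
whose clusters contain the smallest leaf indices wins, so identical input
always yields an identical dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError
from .transforms import DistanceMatrix

__all__ = ["Dendrogram", "ClusterAssignment", "ward_cluster", "cut_dendrogram",
           "cophenetic_matrix"]


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    Leaves are numbered 0..n-1 in input order; the i-th merge creates internal
    node n+i.  ``merge_steps`` holds (left, right, height, size) tuples with
    left < right.
    """

    leaf_ids: list
    merge_steps: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merge_steps) != n - 1:
            raise ValidationError(
                f"dendrogram with {n} leaves needs {n - 1} merges, "
                f"got {len(self.merge_steps)}"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage matrix."""
        return np.array(
            [[a, b, h, s] for a, b, h, s in self.merge_steps], dtype=float
        )

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (a, b) for i, (a, b, _, _) in enumerate(self.merge_steps)}

    def leaves_order(self) -> list[int]:
        """Leaf indices in left-to-right dendrogram order."""
        children = self._children()
        root = 2 * self.n_leaves - 2
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                stack.append(b)  # right processed after left
                stack.append(a)
        return order

    def to_newick(self) -> str:
        """Newick serialization with branch lengths = height differences."""
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for i, (_, _, h, _) in enumerate(self.merge_steps):
            heights[self.n_leaves + i] = h

        def label(node: int) -> str:
            return str(self.leaf_ids[node]).replace(" ", "_")

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < self.n_leaves:
                return f"{label(node)}:{bl:.10g}"
            a, b = self._children()[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        root = 2 * self.n_leaves - 2
        a, b = self._children()[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class ClusterAssignment:
    """Flat clustering: sample id -> label in 1..k, labels ordered by
    dendrogram left-to-right leaf order."""

    labels: dict
    k: int

    def as_series(self):
        import pandas as pd

        return pd.Series(self.labels, name="cluster")

    def members(self, label: int) -> list:
        return [s for s, c in self.labels.items() if c == label]


def ward_cluster(distances: DistanceMatrix, variant: str = "D2") -> Dendrogram:
    """Ward agglomeration of a distance matrix via the Lance-Williams update.

    With ``variant="D2"`` the update runs on squared distances

        d2(k, i+j) = [(n_i+n_k) d2(i,k) + (n_j+n_k) d2(j,k) - n_k d2(i,j)]
                     / (n_i + n_j + n_k)

    and heights are reported in original distance units (sqrt of the merge
    cost).  ``variant="D"`` applies the same recurrence to unsquared
    distances.
    """
    if variant not in ("D2", "D"):
        raise ValidationError("ward variant must be 'D2' or 'D'")
    n = len(distances.sample_ids)
    if n < 2:
        raise ValidationError("clustering needs at least 2 samples")
    work = distances.values.astype(float).copy()
    if variant == "D2":
        work = work ** 2

    # active cluster state: node id, size, min leaf index
    active: dict[int, tuple[int, int]] = {i: (1, i) for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = work[i, j]

    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        best_cost = np.inf
        for i in active:
            for j in active:
                if i >= j:
                    continue
                c = dist[key(i, j)]
                if c < best_cost:
                    best_cost = c
                    best = (i, j)
                elif c == best_cost:
                    # deterministic tie-break on the leaf content of the pair
                    mi = min(active[i][1], active[j][1])
                    ma = max(active[i][1], active[j][1])
                    bi = min(active[best[0]][1], active[best[1]][1])
                    ba = max(active[best[0]][1], active[best[1]][1])
                    if (mi, ma) < (bi, ba):
                        best = (i, j)
        i, j = best
        ni, mi = active[i]
        nj, mj = active[j]
        size = ni + nj
        height = float(np.sqrt(best_cost)) if variant == "D2" else float(best_cost)
        merges.append((i, j, height, size))
        new = next_id
        next_id += 1
        cost_ij = dist[key(i, j)]
        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k][0]
            c = (
                (ni + nk) * dist[key(i, k)]
                + (nj + nk) * dist[key(j, k)]
                - nk * cost_ij
            ) / (ni + nj + nk)
            dist[key(new, k)] = c
        for k in list(dist):
            if i in k or j in k:
                del dist[k]
        del active[i], active[j]
        active[new] = (size, min(mi, mj))

    return Dendrogram(list(distances.sample_ids), merges)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly k clusters by undoing the k-1 highest (last) merges.

    Labels run 1..k ordered by left-to-right leaf position, so the leftmost
    cluster in the tree is cluster 1.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    # Ward heights are monotone, so the last k-1 merges are the highest;
    # apply only the first n-k merges.
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(n - k):
        a, b, _, _ = dendrogram.merge_steps[idx]
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node

    order = dendrogram.leaves_order()
    label_of_root: dict[int, int] = {}
    labels: dict = {}
    for leaf in order:
        r = find(leaf)
        if r not in label_of_root:
            label_of_root[r] = len(label_of_root) + 1
        labels[dendrogram.leaf_ids[leaf]] = label_of_root[r]
    return ClusterAssignment(labels, k)


def cophenetic_matrix(dendrogram: Dendrogram) -> DistanceMatrix:
    """Cophenetic distances: the merge height at which each pair first joins."""
    n = dendrogram.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    for idx, (a, b, h, _) in enumerate(dendrogram.merge_steps):
        for x in members[a]:
            for y in members[b]:
                coph[x, y] = coph[y, x] = h
        members[n + idx] = members.pop(a) + members.pop(b)
    return DistanceMatrix(list(dendrogram.leaf_ids), coph)
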
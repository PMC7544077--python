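"""Agglomerative hierarchical clustering and the two-cluster dendrogram cut.

The agglomeration is an explicit Lance-Williams loop so that the two Ward
variants used in R's ``hclust`` are reproduced exactly:

``complete``
    new-cluster-to-k dissimilarity = max of the children's.
``ward_d``
    the Ward update applied to the dissimilarities *as given* (R's
    ``ward.D``; heights reported on the same scale).
``ward_d2``
    the Ward update applied to *squared* dissimilarities with merge
    heights reported on the square-root scale (R's ``ward.D2``, equal to
    scipy's ``ward`` on Euclidean input).

Ties in the minimum pairwise dissimilarity are broken by the smallest
(row, column) pair index, making the merge order a pure function of the
input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LINKAGES
from .distances import DistanceMatrix


@dataclass
class MergeTree:
    """Agglomeration history: n-1 merges over n leaves.

    Nodes are numbered scipy-style: leaves ``0..n-1`` in input order,
    internal nodes ``n..2n-2`` in merge order.  Each merge record is
    ``(child_a, child_b, height)`` with ``child_a < child_b``.
    """

    merges: list[tuple[int, int, float]]
    leaf_ids: list[str]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def members(self, node: int) -> list[int]:
        """Leaf indices under ``node``."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b, _ = self.merges[v - n]
                stack.extend((a, b))
        return sorted(out)


def agglomerate(dm: DistanceMatrix, linkage: str) -> MergeTree:
    """Lance-Williams agglomeration of a distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    if not np.all(np.isfinite(dm.entries)):
        raise ValueError("non-finite distances")

    # the matrix the LW updates operate on (squared for ward_d2)
    work = dm.entries.astype(float) ** 2 if linkage == "ward_d2" else dm.entries.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # positions still alive, in stable order
    node_of = list(range(n))  # position -> current node id
    sizes = np.ones(n)
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        best = (np.inf, -1, -1)
        for ai in range(len(active)):
            i = active[ai]
            row = work[i]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                if row[j] < best[0]:
                    best = (row[j], i, j)
        h, i, j = best
        height = float(np.sqrt(h)) if linkage == "ward_d2" else float(h)
        a, b = sorted((node_of[i], node_of[j]))
        merges.append((a, b, height))

        for k in active:
            if k in (i, j):
                continue
            if linkage == "complete":
                new = max(work[i, k], work[j, k])
            else:  # ward update on the working scale
                si, sj, sk = sizes[i], sizes[j], sizes[k]
                new = ((si + sk) * work[i, k] + (sj + sk) * work[j, k] - sk * work[i, j]) / (
                    si + sj + sk
                )
            work[i, k] = work[k, i] = new
        sizes[i] += sizes[j]
        node_of[i] = n + step
        active.remove(j)
        work[j, :] = work[:, j] = np.inf
    return MergeTree(merges=merges, leaf_ids=list(dm.ids), linkage=linkage)


@dataclass
class ClusterAssignment:
    """Binary partition from cutting the dendrogram below the root.

    Label 1 is the cluster containing the lexicographically smallest
    sequence id, so labels are deterministic given the inputs.
    """

    labels: dict[str, int]
    representation: str = ""
    distance: str = ""
    linkage: str = ""

    def label_array(self, ids) -> np.ndarray:
        return np.array([self.labels[i] for i in ids], dtype=int)

    def sizes(self) -> tuple[int, int]:
        vals = list(self.labels.values())
        return vals.count(1), vals.count(2)


def cut_two(tree: MergeTree, **provenance) -> ClusterAssignment:
    """Remove the final merge; its two subtrees are the two clusters."""
    n = tree.n_leaves
    a, b, _ = tree.merges[-1]
    group_a = [tree.leaf_ids[i] for i in tree.members(a)]
    group_b = [tree.leaf_ids[i] for i in tree.members(b)]
    if min(group_a) > min(group_b):
        group_a, group_b = group_b, group_a
    labels = {i: 1 for i in group_a}
    labels.update({i: 2 for i in group_b})
    return ClusterAssignment(labels=labels, **provenance)


def merge_list_frame(tree: MergeTree) -> pd.DataFrame:
    """Merge history as a tidy table (child_a, child_b, height)."""
    return pd.DataFrame(tree.merges, columns=["child_a", "child_b", "height"])


def to_newick(tree: MergeTree) -> str:
    """Newick text with branch lengths from merge-height differences.

    Negative branch lengths can occur for ward_d, whose heights are not
    guaranteed monotone; they are clamped to 0 for viewer compatibility.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for s, (_, _, h) in enumerate(tree.merges):
        heights[n + s] = h

    def render(node: int, parent_height: float) -> str:
        bl = max(parent_height - heights[node], 0.0)
        if node < n:
            return f"{tree.leaf_ids[node]}:{bl:.12g}"
        a, b, h = tree.merges[node - n]
        return f"({render(a, h)},{render(b, h)}):{bl:.12g}"

    root = 2 * n - 2
    a, b, h = tree.merges[-1]
    return f"({render(a, h)},{render(b, h)});"
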
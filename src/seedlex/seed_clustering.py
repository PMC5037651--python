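"""Agglomerative clustering of seed-term direction vectors.

Starting from singleton clusters, the pair of clusters whose centroids have
the largest cosine similarity is merged, centroids being the unnormalised
arithmetic mean of the member vectors (cosine to a centroid is
scale-invariant, so normalisation would not change any ranking).  Merging is
repeated until a single root remains.

Size-bounded partitions are read off the tree: the cut at maximum cluster
size ``L`` keeps the highest nodes with at most ``L`` members, so ``L = 1``
treats every seed as its own cluster and ``L = |seeds|`` yields the root
alone — sweeping ``L`` upward walks from the leaves to the root.

Ties in the maximal centroid similarity are broken deterministically: the
candidate pair whose lexicographically smallest member is smallest wins (the
other cluster's smallest member is the secondary key).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .semantic_space import SemanticSpace, ZeroVectorError

__all__ = [
    "ClusterNode",
    "ClusterPartition",
    "SeedSet",
    "MissingSeedError",
    "agglomerate",
    "cut_by_max_size",
    "sweep_levels",
    "collect_nodes",
    "to_newick",
    "to_outline",
]


class MissingSeedError(KeyError):
    """One or more seed terms have no vector in the space."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"seed terms missing from the space: {list(missing)}")


@dataclass(frozen=True, eq=False)
class ClusterNode:
    """A node of the merge tree.

    ``members`` is the sorted tuple of seed terms below the node; the
    centroid is the arithmetic mean of the members' direction vectors and is
    recomputable from the leaves.  Leaves have ``merge_order`` 0; merges are
    numbered 1, 2, … so the root carries the largest value.
    """

    members: Tuple[str, ...]
    centroid: np.ndarray
    children: Tuple["ClusterNode", ...]  # empty for leaves, else exactly two
    merge_order: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["ClusterNode"]:
        out: List[ClusterNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out


@dataclass(frozen=True)
class SeedSet:
    """Seed terms of one semantic category."""

    category: str
    terms: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("seed terms must be unique")
        if not self.terms:
            raise ValueError("seed set must be non-empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


@dataclass(frozen=True)
class ClusterPartition:
    """The cut of a dendrogram at maximum cluster size ``max_size``."""

    max_size: int
    clusters: Tuple[ClusterNode, ...]

    @property
    def centroids(self) -> List[np.ndarray]:
        return [c.centroid for c in self.clusters]

    def members(self) -> List[Tuple[str, ...]]:
        return [c.members for c in self.clusters]


def _cosine_to_all(centroid: np.ndarray, others: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(others, axis=1)
    n0 = np.linalg.norm(centroid)
    return (others @ centroid) / (norms * n0)


def agglomerate(seeds: SeedSet, space: SemanticSpace) -> ClusterNode:
    """Build the full merge tree over the seed terms' direction vectors."""
    missing = [t for t in seeds.terms if t not in space]
    if missing:
        raise MissingSeedError(missing)
    vectors = np.stack([space.vector(t) for t in seeds.terms]).astype(np.float64)
    if (np.linalg.norm(vectors, axis=1) == 0).any():
        zero = [t for t, v in zip(seeds.terms, vectors) if not np.linalg.norm(v)]
        raise ZeroVectorError(f"seed terms with zero vectors: {zero}")

    nodes: List[ClusterNode] = [
        ClusterNode((t,), vectors[i].copy(), (), 0)
        for i, t in enumerate(seeds.terms)
    ]
    sums = [vectors[i].copy() for i in range(len(nodes))]
    counts = [1] * len(nodes)

    n = len(nodes)
    if n == 1:
        return nodes[0]

    cents = np.stack([node.centroid for node in nodes])
    sim = np.full((n, n), -np.inf)
    normed = cents / np.linalg.norm(cents, axis=1, keepdims=True)
    sim_full = normed @ normed.T
    iu = np.triu_indices(n, k=1)
    sim[iu] = sim_full[iu]

    active = list(range(n))  # indices into nodes/sums/counts; sim uses them too

    for merge_order in range(1, n):
        best = -np.inf
        best_pair: Optional[Tuple[int, int]] = None
        # scan upper triangle restricted to active indices
        sub = sim[np.ix_(active, active)]
        m = len(active)
        tri = np.triu_indices(m, k=1)
        vals = sub[tri]
        best = vals.max()
        cand = np.nonzero(vals == best)[0]
        # deterministic tie-break on the lexicographically smallest members
        def key(ci: int) -> Tuple[str, str]:
            i, j = active[tri[0][ci]], active[tri[1][ci]]
            a, b = nodes[i].members[0], nodes[j].members[0]
            return (min(a, b), max(a, b))

        chosen = min(cand, key=key)
        i, j = active[tri[0][chosen]], active[tri[1][chosen]]

        new_sum = sums[i] + sums[j]
        new_count = counts[i] + counts[j]
        centroid = new_sum / new_count
        left, right = nodes[i], nodes[j]
        if right.members[0] < left.members[0]:
            left, right = right, left
        node = ClusterNode(
            tuple(sorted(left.members + right.members)),
            centroid,
            (left, right),
            merge_order,
        )
        nodes.append(node)
        sums.append(new_sum)
        counts.append(new_count)
        new_idx = len(nodes) - 1

        active = [a for a in active if a not in (i, j)]
        # grow the similarity matrix by one row/column
        grown = np.full((new_idx + 1, new_idx + 1), -np.inf)
        grown[:new_idx, :new_idx] = sim
        sim = grown
        if active:
            others = np.stack([nodes[a].centroid for a in active])
            cos = _cosine_to_all(centroid, others)
            for a, c in zip(active, cos):
                lo, hi = min(a, new_idx), max(a, new_idx)
                sim[lo, hi] = c
        active.append(new_idx)

    return nodes[-1]


def cut_by_max_size(root: ClusterNode, max_size: int) -> ClusterPartition:
    """Highest tree nodes with at most ``max_size`` members.

    A node is kept iff its member count is ≤ ``max_size`` while its parent
    (if any) exceeds it; the kept clusters partition the seed set.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    kept: List[ClusterNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.size <= max_size:
            kept.append(node)
        else:
            stack.extend(reversed(node.children))
    kept.sort(key=lambda c: c.members[0])
    return ClusterPartition(max_size, tuple(kept))


def sweep_levels(root: ClusterNode) -> List[ClusterPartition]:
    """Partitions for L = 1 … |seeds|, deduplicated to levels that change."""
    partitions: List[ClusterPartition] = []
    previous = None
    for level in range(1, root.size + 1):
        part = cut_by_max_size(root, level)
        signature = part.members()
        if signature != previous:
            partitions.append(part)
            previous = signature
    return partitions


def collect_nodes(root: ClusterNode) -> List[ClusterNode]:
    """All nodes of the tree, leaves first, in deterministic order."""
    out: List[ClusterNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(reversed(node.children))
    out.sort(key=lambda n: (n.merge_order, n.members[0]))
    return out


def to_newick(root: ClusterNode) -> str:
    """Nested-parenthesis (Newick-style) rendering with member labels."""

    def render(node: ClusterNode) -> str:
        if node.is_leaf:
            return node.members[0]
        return "(" + ",".join(render(c) for c in node.children) + ")"

    return render(root) + ";"


def to_outline(root: ClusterNode, indent: str = "  ") -> str:
    """Indented text outline of the merge tree for inspection."""
    lines: List[str] = []

    def walk(node: ClusterNode, depth: int) -> None:
        label = node.members[0] if node.is_leaf else f"[{node.size} terms]"
        lines.append(indent * depth + label)
        for child in node.children:
            walk(child, depth + 1)

    walk(root, 0)
    return "\n".join(lines)
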
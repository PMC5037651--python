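"""Independent reference implementations used to check the fast paths.

Everything here is deliberately naive: plain nested loops and explicit
sorting, no sharing of code with the package's vectorised implementations
beyond the index-vector primitive itself.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

from seedlex.semantic_space import SpaceConfig, make_index_vector


def brute_force_vectors(
    sentences: Sequence[Sequence[str]], config: SpaceConfig
) -> Dict[str, np.ndarray]:
    """Nested-loop accumulation of semantic vectors for every unit.

    Walks every (target, context) pair inside the window explicitly and adds
    the context's rotated index vector with np.roll.  Returns vectors for all
    units regardless of the frequency cutoff.
    """
    vectors: Dict[str, np.ndarray] = {}
    for sent in sentences:
        for i, target in enumerate(sent):
            if target not in vectors:
                vectors[target] = np.zeros(config.dimensionality, dtype=np.int64)
            for j, context in enumerate(sent):
                if i == j or abs(i - j) > config.window:
                    continue
                iv = make_index_vector(context, config).to_dense()
                if config.use_permutation:
                    steps = abs(i - j) if config.rotate_by_offset else 1
                    shift = -steps if j < i else steps
                    iv = np.roll(iv, shift)
                vectors[target] += iv
    return vectors


def brute_force_counts(
    sentences: Sequence[Sequence[str]], count_isolated: bool = False
) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for sent in sentences:
        if len(sent) < 2 and not count_isolated:
            continue
        for unit in sent:
            counts[unit] = counts.get(unit, 0) + 1
    return counts


def _cos(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def brute_force_merge_sequence(
    labels: Sequence[str], vectors: np.ndarray
) -> List[Tuple[Tuple[str, ...], Tuple[str, ...]]]:
    """O(n^3) agglomeration: recompute every centroid and every pairwise
    centroid cosine from scratch at each step.

    Ties on the maximal cosine are broken by the pair whose lexicographically
    smallest member is smallest (secondary key: the other cluster's smallest
    member).  Returns the merge sequence as sorted member tuples.
    """
    clusters: List[List[int]] = [[i] for i in range(len(labels))]
    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...]]] = []
    while len(clusters) > 1:
        best = None
        best_key = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = np.mean(vectors[clusters[a]], axis=0)
                cb = np.mean(vectors[clusters[b]], axis=0)
                sim = _cos(ca, cb)
                ma = min(labels[i] for i in clusters[a])
                mb = min(labels[i] for i in clusters[b])
                key = (-sim, min(ma, mb), max(ma, mb))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best
        members_a = tuple(sorted(labels[i] for i in clusters[a]))
        members_b = tuple(sorted(labels[i] for i in clusters[b]))
        if members_b[0] < members_a[0]:
            members_a, members_b = members_b, members_a
        merges.append((members_a, members_b))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def sort_based_percentile(values: Sequence[float], p: float) -> float:
    """Nearest-rank percentile by explicit sort and 1-based indexing."""
    ordered = sorted(float(v) for v in values)
    rank = math.ceil(p / 100.0 * len(ordered))
    rank = max(1, min(rank, len(ordered)))
    return ordered[rank - 1]
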
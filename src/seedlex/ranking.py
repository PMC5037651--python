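"""Scoring and ranking of unknown corpus units against a seed set.

Two scores are implemented.  *Cluster similarity* is the largest cosine
between a candidate's direction vector and any centroid of a seed-cluster
partition; at partition level 1 it reduces to the nearest-seed score and at
level |S| to the cosine against the global seed centroid.  *Summed
similarity* is the sum of cosines between the candidate and every individual
seed vector.

The candidate universe is every unit above the frequency cutoff that is not
a seed term — held-out vocabulary terms remain candidates, since they are
exactly what the evaluation must retrieve.  Rankings are deterministic:
scores are sorted in decreasing order with ties broken by ascending
lexicographic term order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .seed_clustering import ClusterPartition, SeedSet
from .semantic_space import SemanticSpace, ZeroVectorError, cosine

__all__ = [
    "RankedCandidateList",
    "ConfigurationError",
    "cluster_similarity",
    "summed_similarity",
    "rank_candidates",
]

METHODS = ("cluster", "summed", "random")


class ConfigurationError(ValueError):
    """Invalid method/partition combination."""


@dataclass(frozen=True)
class RankedCandidateList:
    """Unknown terms ordered by decreasing similarity score.

    ``method`` is ``cluster`` (with the partition's maximum cluster size as
    ``level``), ``summed``, or ``random`` (the null model used for
    calibration).  Scores are non-increasing down the list; equal scores are
    ordered by ascending term.
    """

    method: str
    level: Optional[int]
    entries: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def terms(self) -> List[str]:
        return [t for t, _ in self.entries]

    def top(self, k: int) -> "RankedCandidateList":
        return RankedCandidateList(self.method, self.level, self.entries[:k])


def cluster_similarity(u: np.ndarray, partition: ClusterPartition) -> float:
    """Largest cosine between ``u`` and any centroid of the partition."""
    if not partition.clusters:
        raise ConfigurationError("partition has no clusters")
    return max(cosine(u, c) for c in partition.centroids)


def summed_similarity(u: np.ndarray, seeds: SeedSet, space: SemanticSpace) -> float:
    """Sum of cosines between ``u`` and every seed term's vector."""
    if not seeds.terms:
        raise ConfigurationError("seed set is empty")
    return float(sum(cosine(u, space.vector(s)) for s in seeds.terms))


def _sorted_entries(
    terms: Sequence[str], scores: np.ndarray
) -> Tuple[Tuple[str, float], ...]:
    # terms arrive in ascending lexicographic order, so a stable sort on
    # descending score realises the documented tie-break.
    order = np.argsort(-scores, kind="stable")
    return tuple((terms[i], float(scores[i])) for i in order)


def rank_candidates(
    space: SemanticSpace,
    seeds: SeedSet,
    method: str = "cluster",
    partition: Optional[ClusterPartition] = None,
    rng: Optional[np.random.Generator] = None,
    top: Optional[int] = None,
) -> RankedCandidateList:
    """Rank every non-seed unit of the space by the chosen score.

    ``method='cluster'`` requires a partition; ``method='random'`` assigns
    i.i.d. uniform scores from ``rng`` and exists to calibrate the evaluation
    against the analytic random baseline.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    if method == "cluster" and partition is None:
        raise ConfigurationError("method 'cluster' requires a partition")
    if method == "random" and rng is None:
        raise ConfigurationError("method 'random' requires an rng")
    missing = [t for t in seeds.terms if t not in space]
    if missing:
        raise ConfigurationError(f"seed terms missing from space: {missing}")

    seed_set = set(seeds.terms)
    universe = [t for t in space.terms if t not in seed_set]  # ascending terms
    if not universe:
        return RankedCandidateList(
            method, partition.max_size if partition else None, ()
        )
    rows = np.array([space.row(t) for t in universe])
    U = space.matrix[rows].astype(np.float64)
    norms = np.linalg.norm(U, axis=1)
    if (norms == 0).any():
        zero = [universe[i] for i in np.nonzero(norms == 0)[0]]
        raise ZeroVectorError(f"candidates with zero vectors: {zero[:5]}")
    Un = U / norms[:, None]

    level: Optional[int] = None
    if method == "cluster":
        assert partition is not None
        level = partition.max_size
        C = np.stack(partition.centroids)
        Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
        scores = (Un @ Cn.T).max(axis=1)
    elif method == "summed":
        S = np.stack([space.vector(t) for t in seeds.terms]).astype(np.float64)
        Sn = S / np.linalg.norm(S, axis=1, keepdims=True)
        scores = Un @ Sn.sum(axis=0)
    else:  # random
        assert rng is not None
        scores = rng.random(len(universe))

    entries = _sorted_entries(universe, scores)
    if top is not None:
        entries = entries[:top]
    return RankedCandidateList(method, level, entries)
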
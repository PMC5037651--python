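"""Random-indexing semantic space with random-permutation direction vectors.

Every semantic unit of the corpus receives a sparse ternary *index vector*:
``k`` non-zero entries (half +1, half −1) at positions drawn from a generator
seeded by a stable hash of ``(master_seed, term)``, so index vectors are
reproducible across runs and independent of corpus streaming order.  With a
sufficiently large dimensionality the index vectors of distinct units are
nearly orthogonal with high probability.

A unit's *semantic vector* is the sum of the index vectors of the units it
co-occurs with inside a symmetric window that never crosses a sentence
boundary (no boundary markers are added), all context positions weighted
equally.  When ``use_permutation`` is on, a left-context unit's index vector
is rotated one step to the left and a right-context unit's one step to the
right before adding, encoding word order; the resulting vectors are the
*direction vectors* used throughout the pipeline.  Entries are therefore
always integers.

Units occurring at most ``min_frequency`` times (counted, by default, only in
sentences with at least two units — an isolated unit has no context) are not
given a semantic vector, but their index vectors still contribute to the
vectors of other units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

__all__ = [
    "SpaceConfig",
    "IndexVector",
    "SemanticSpace",
    "make_index_vector",
    "permute",
    "count_frequencies",
    "build_space",
    "cosine",
    "EmptyCorpusError",
    "ZeroVectorError",
]


class EmptyCorpusError(ValueError):
    """build_space received no sentences."""


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for a zero vector."""


@dataclass(frozen=True)
class SpaceConfig:
    """Hyperparameters of the random-indexing space.

    dimensionality
        Length of index and semantic vectors (default 2000).
    nonzeros
        Number of non-zero entries per index vector; must be even so the
        signs balance (default 10).
    window
        Context positions considered on each side of the target (default 1;
        8 is the other setting of interest).
    use_permutation
        Rotate context index vectors one step left/right before adding
        (direction vectors).  Off gives plain context vectors.
    min_frequency
        Strict lower bound: a unit receives a semantic vector only if it
        occurs *more than* this many times (default 50).
    rotate_by_offset
        Optional variant: rotate by the window offset instead of a single
        step.  Off by default — one step regardless of distance.
    count_isolated
        Count occurrences in single-unit sentences toward the frequency
        cutoff.  Off by default: an isolated unit has no context.
    """

    dimensionality: int = 2000
    nonzeros: int = 10
    window: int = 1
    use_permutation: bool = True
    min_frequency: int = 50
    master_seed: int = 0
    rotate_by_offset: bool = False
    count_isolated: bool = False

    def __post_init__(self) -> None:
        if self.dimensionality < 1:
            raise ValueError("dimensionality must be positive")
        if self.nonzeros < 2 or self.nonzeros % 2:
            raise ValueError("nonzeros must be a positive even integer")
        if self.nonzeros > self.dimensionality:
            raise ValueError("nonzeros cannot exceed dimensionality")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_frequency < 0:
            raise ValueError("min_frequency must be >= 0")


@dataclass(frozen=True, eq=False)
class IndexVector:
    """Sparse ternary random vector: k distinct positions, balanced signs."""

    dimension: int
    positions: np.ndarray  # int64, shape (k,)
    signs: np.ndarray  # int8, shape (k,), k/2 of each sign

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.dimension, dtype=np.int64)
        v[self.positions] = self.signs
        return v


def _term_seed(master_seed: int, term: str) -> int:
    digest = hashlib.sha256(
        f"{master_seed}\x1f{term}".encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:16], "big")


def _draw_positions_signs(
    term: str, config: SpaceConfig
) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.Generator(np.random.PCG64(_term_seed(config.master_seed, term)))
    positions = rng.choice(config.dimensionality, size=config.nonzeros, replace=False)
    k = config.nonzeros
    signs = np.empty(k, dtype=np.int8)
    signs[: k // 2] = 1
    signs[k // 2 :] = -1
    return positions.astype(np.int64), signs


def make_index_vector(term: str, config: SpaceConfig) -> IndexVector:
    """Deterministic index vector for ``term`` under ``config``.

    Identical ``(master_seed, term)`` pairs give identical vectors across
    runs and platforms; signs are balanced so every index vector sums to 0.
    """
    if not term:
        raise ValueError("term must be non-empty")
    positions, signs = _draw_positions_signs(term, config)
    return IndexVector(config.dimensionality, positions, signs)


def permute(vector: np.ndarray, direction: str, steps: int = 1) -> np.ndarray:
    """Circularly rotate ``vector`` by ``steps`` positions.

    ``right`` moves entry *i* to *(i+steps) mod d*; ``left`` is the inverse.
    Rotation is a permutation, so all norms are preserved.
    """
    if direction == "right":
        return np.roll(vector, steps)
    if direction == "left":
        return np.roll(vector, -steps)
    raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")


def count_frequencies(
    sentences: Iterable[Sequence[str]], count_isolated: bool = False
) -> Dict[str, int]:
    """Occurrence counts per unit.

    By default occurrences in single-unit sentences are not counted: such a
    unit appears in no context window.
    """
    counts: Dict[str, int] = {}
    for sent in sentences:
        if not count_isolated and len(sent) < 2:
            continue
        for unit in sent:
            counts[unit] = counts.get(unit, 0) + 1
    return counts


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors: u·v / (‖u‖‖v‖).

    Raises :class:`ZeroVectorError` for a zero vector — the similarity is
    undefined, never silently 0.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


class SemanticSpace:
    """The queryable model: per-unit frequencies plus direction vectors.

    Vectors are stored as an integer matrix with one row per unit above the
    frequency cutoff, rows ordered by term so iteration is deterministic.
    """

    def __init__(
        self,
        config: SpaceConfig,
        frequencies: Dict[str, int],
        terms: Sequence[str],
        matrix: np.ndarray,
    ):
        self.config = config
        self.frequencies = dict(frequencies)
        self.terms: Tuple[str, ...] = tuple(terms)
        if matrix.shape != (len(self.terms), config.dimensionality):
            raise ValueError("matrix shape does not match terms/config")
        self.matrix = np.asarray(matrix, dtype=np.int64)
        self._row = {t: i for i, t in enumerate(self.terms)}
        for t in self.terms:
            if self.frequencies.get(t, 0) <= config.min_frequency:
                raise ValueError(
                    f"term {t!r} has a vector but frequency "
                    f"{self.frequencies.get(t, 0)} <= cutoff"
                )

    # -- queries ------------------------------------------------------------

    @property
    def V(self) -> int:
        """Number of units above the frequency cutoff (vector rows)."""
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._row

    def __len__(self) -> int:
        return len(self.terms)

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.matrix[self._row[term]]
        except KeyError:
            raise KeyError(
                f"term {term!r} is not in the space (below cutoff or unseen)"
            ) from None

    def row(self, term: str) -> int:
        return self._row[term]

    def similarity(self, a: str, b: str) -> float:
        return cosine(self.vector(a), self.vector(b))

    def index_vector(self, term: str) -> IndexVector:
        return make_index_vector(term, self.config)

    # -- persistence ----------------------------------------------------------

    _MAGIC = "#seedlex-space\t1"

    def save(self, path: str | Path) -> None:
        """Persist as a text container; round-trips bit-exactly (integers)."""
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self._MAGIC + "\n")
            fh.write(json.dumps(asdict(self.config), sort_keys=True) + "\n")
            freq_terms = sorted(self.frequencies)
            fh.write(f"{len(freq_terms)}\t{len(self.terms)}\n")
            for t in freq_terms:
                fh.write(f"{t}\t{self.frequencies[t]}\n")
            for i, t in enumerate(self.terms):
                fh.write(t + "\t" + ",".join(map(str, self.matrix[i])) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SemanticSpace":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            magic = fh.readline().rstrip("\n")
            if magic != cls._MAGIC:
                raise ValueError(f"{path}: not a seedlex space file")
            config = SpaceConfig(**json.loads(fh.readline()))
            n_freq, n_vec = map(int, fh.readline().split("\t"))
            frequencies: Dict[str, int] = {}
            for _ in range(n_freq):
                term, count = fh.readline().rstrip("\n").split("\t")
                frequencies[term] = int(count)
            terms: List[str] = []
            rows = np.zeros((n_vec, config.dimensionality), dtype=np.int64)
            for i in range(n_vec):
                term, values = fh.readline().rstrip("\n").split("\t")
                terms.append(term)
                rows[i] = np.array(
                    [int(x) for x in values.split(",")], dtype=np.int64
                )
        return cls(config, frequencies, terms, rows)


def _index_matrix(
    positions: np.ndarray, signs: np.ndarray, dimensionality: int, shift: int
) -> sparse.csr_matrix:
    """CSR matrix of (rotated) index vectors, one row per unit."""
    n, k = positions.shape
    cols = (positions + shift) % dimensionality
    rows = np.repeat(np.arange(n, dtype=np.int64), k)
    return sparse.coo_matrix(
        (signs.ravel().astype(np.int64), (rows, cols.ravel())),
        shape=(n, dimensionality),
    ).tocsr()


def build_space(
    sentences: Iterable[Sequence[str]], config: SpaceConfig
) -> SemanticSpace:
    """Accumulate direction vectors over a pre-processed corpus.

    For every occurrence of a target at position *i* and every context
    position *j ≠ i* with ``|i−j| <= window`` in the same sentence, the
    (rotated) index vector of the context unit is added to the target's
    semantic vector.  Vectors of units at or below the frequency cutoff are
    discarded afterwards, but their contributions to other vectors remain.
    """
    sents = [list(s) for s in sentences]
    sents = [s for s in sents if s]
    if not sents:
        raise EmptyCorpusError("cannot build a space from zero sentences")

    unit_id: Dict[str, int] = {}
    flat: List[int] = []
    lengths = np.empty(len(sents), dtype=np.int64)
    for si, sent in enumerate(sents):
        lengths[si] = len(sent)
        for unit in sent:
            uid = unit_id.get(unit)
            if uid is None:
                uid = len(unit_id)
                unit_id[unit] = uid
            flat.append(uid)
    ids = np.asarray(flat, dtype=np.int64)
    n_units = len(unit_id)
    sid = np.repeat(np.arange(len(sents), dtype=np.int64), lengths)

    if config.count_isolated:
        counts = np.bincount(ids, minlength=n_units)
    else:
        in_context = np.repeat(lengths >= 2, lengths)
        counts = np.bincount(ids[in_context], minlength=n_units)

    units = [""] * n_units
    for term, uid in unit_id.items():
        units[uid] = term
    frequencies = {units[uid]: int(counts[uid]) for uid in range(n_units)}

    above_terms = sorted(t for t in units if frequencies[t] > config.min_frequency)
    row_map = np.full(n_units, -1, dtype=np.int64)
    for r, t in enumerate(above_terms):
        row_map[unit_id[t]] = r
    n_above = len(above_terms)

    # (target, context) pairs grouped by the rotation shift of the context
    # index vector: left context → −step, right context → +step.
    groups: Dict[int, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for offset in range(1, config.window + 1):
        if offset >= len(ids):
            break
        a = ids[:-offset]
        b = ids[offset:]
        same = sid[:-offset] == sid[offset:]
        if not same.any():
            continue
        if config.use_permutation:
            step = offset if config.rotate_by_offset else 1
        else:
            step = 0
        # b is the target with a as left context; a is the target with b right
        groups.setdefault(-step, []).append((b[same], a[same]))
        groups.setdefault(+step, []).append((a[same], b[same]))

    positions = np.empty((n_units, config.nonzeros), dtype=np.int64)
    signs = np.empty((n_units, config.nonzeros), dtype=np.int8)
    for uid in range(n_units):
        positions[uid], signs[uid] = _draw_positions_signs(units[uid], config)

    matrix = np.zeros((n_above, config.dimensionality), dtype=np.int64)
    for shift, pair_lists in sorted(groups.items()):
        targets = np.concatenate([p[0] for p in pair_lists])
        contexts = np.concatenate([p[1] for p in pair_lists])
        rows = row_map[targets]
        keep = rows >= 0
        if not keep.any():
            continue
        cooc = sparse.coo_matrix(
            (
                np.ones(int(keep.sum()), dtype=np.int64),
                (rows[keep], contexts[keep]),
            ),
            shape=(n_above, n_units),
        ).tocsr()
        idx = _index_matrix(positions, signs, config.dimensionality, shift)
        matrix += (cooc @ idx).toarray()

    return SemanticSpace(config, frequencies, above_terms, matrix)
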
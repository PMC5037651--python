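"""Bootstrap fold evaluation of the vocabulary-expansion pipeline.

The eligible vocabulary of a category (its terms that pass the frequency
cutoff) is repeatedly split into a seed set of fixed size and an evaluation
set of the remaining *n* terms.  For every fold the seeds are clustered, the
unknown units ranked, and recall of the evaluation terms measured among the
top *n*, 2n, …, 10n candidates.  Folds are aggregated into mean recall,
empirical 2.5 %/97.5 % percentiles (nearest rank) and population variance per
multiple, per ranking setting.

The analytic random baseline: a randomly ordered list of the V eligible
units contains on average t·n/V reference terms among its top t entries, so
expected recall at t is t/V.

Per-term retrieval profiling and the unique-top-candidate list reduction are
recomputable from the per-fold records stored on the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .corpus_io import TermList
from .ranking import ConfigurationError
from .seed_clustering import SeedSet, agglomerate, collect_nodes, cut_by_max_size
from .semantic_space import SemanticSpace, ZeroVectorError

__all__ = [
    "FoldSplit",
    "RecallCurve",
    "EvaluationResult",
    "FoldError",
    "make_folds",
    "recall_at",
    "summarize",
    "nearest_rank_percentile",
    "random_baseline",
    "eligible_vocabulary",
    "evaluate_category",
    "retrieval_profile",
    "unique_top_candidates",
]

Setting = Tuple[str, Optional[int]]


class FoldError(ValueError):
    """The vocabulary cannot support the requested seed/evaluation split."""


@dataclass(frozen=True)
class FoldSplit:
    """One random seed/evaluation split of the eligible vocabulary."""

    fold_id: int
    seed_terms: Tuple[str, ...]
    eval_terms: Tuple[str, ...]


@dataclass(frozen=True)
class RecallCurve:
    """Recall of one fold's evaluation terms at each multiple of n."""

    fold_id: int
    recall_at: Dict[int, float]


def make_folds(
    vocab: Union[TermList, Sequence[str]],
    seed_size: int = 100,
    n_folds: int = 500,
    master_seed: int = 0,
) -> List[FoldSplit]:
    """Independent uniform draws of ``seed_size`` seeds per fold.

    Seeds are sampled without replacement (a duplicated seed is meaningless
    for clustering); the evaluation set is the complement.  Fully
    reproducible from ``master_seed``.
    """
    terms = list(vocab.terms) if isinstance(vocab, TermList) else list(vocab)
    if len(terms) <= seed_size:
        raise FoldError(
            f"vocabulary has {len(terms)} terms; need more than seed_size={seed_size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    folds = []
    for fold_id in range(n_folds):
        perm = rng.permutation(len(terms))
        seed_idx = np.sort(perm[:seed_size])
        eval_idx = np.sort(perm[seed_size:])
        folds.append(
            FoldSplit(
                fold_id,
                tuple(terms[i] for i in seed_idx),
                tuple(terms[i] for i in eval_idx),
            )
        )
    return folds


def recall_at(
    ranked,
    eval_terms: Iterable[str],
    n: Optional[int] = None,
    multiples: Sequence[int] = tuple(range(1, 11)),
    fold_id: int = 0,
) -> RecallCurve:
    """Recall of ``eval_terms`` among the top m·n ranked candidates.

    ``ranked`` is a RankedCandidateList or a plain sequence of terms in rank
    order.  ``n`` defaults to the number of evaluation terms.  An evaluation
    term absent from the candidate list counts as not retrieved at every
    multiple; a list shorter than m·n is used whole.
    """
    terms = ranked.terms() if hasattr(ranked, "terms") else list(ranked)
    eval_set = set(eval_terms)
    if n is None:
        n = len(eval_set)
    if n <= 0:
        raise ValueError("n must be positive")
    rank_of = {}
    for r, t in enumerate(terms):
        if t in eval_set and t not in rank_of:
            rank_of[t] = r
    ranks = np.array(sorted(rank_of.values()), dtype=np.int64)
    curve = {
        int(m): float(np.count_nonzero(ranks < m * n)) / n for m in multiples
    }
    return RecallCurve(fold_id, curve)


def nearest_rank_percentile(values: Sequence[float], p: float) -> float:
    """Nearest-rank percentile: the ⌈p/100·N⌉-th smallest value."""
    ordered = np.sort(np.asarray(values, dtype=np.float64))
    if ordered.size == 0:
        raise ValueError("need at least one value")
    rank = max(1, math.ceil(p / 100.0 * ordered.size))
    return float(ordered[min(rank, ordered.size) - 1])


def _stats_from_values(values: np.ndarray) -> Dict[str, float]:
    return {
        "mean": float(values.mean()),
        "p2_5": nearest_rank_percentile(values, 2.5),
        "p97_5": nearest_rank_percentile(values, 97.5),
        "variance": float(values.var()),  # population variance over folds
    }


def summarize(curves: Sequence[RecallCurve]) -> Dict[int, Dict[str, float]]:
    """Per-multiple mean, 2.5 %/97.5 % percentiles and population variance."""
    if not curves:
        raise ValueError("need at least one recall curve")
    multiples = sorted(curves[0].recall_at)
    out: Dict[int, Dict[str, float]] = {}
    for m in multiples:
        values = np.array([c.recall_at[m] for c in curves], dtype=np.float64)
        out[m] = _stats_from_values(values)
    return out


def random_baseline(
    n: int, V: int, multiples: Sequence[int] = tuple(range(1, 11))
) -> Dict[int, Dict[str, float]]:
    """Expected performance of a randomly ordered list of the V eligible units.

    At t = m·n the expected number of retrieved reference terms is t·n/V and
    expected recall t/V (both capped at their attainable maxima).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > V:
        raise ValueError(f"n={n} exceeds the number of eligible units V={V}")
    out = {}
    for m in multiples:
        t = m * n
        out[int(m)] = {
            "recall": min(1.0, t / V),
            "expected_count": min(float(n), t * n / V),
        }
    return out


def eligible_vocabulary(space: SemanticSpace, vocab: TermList) -> TermList:
    """Vocabulary terms that pass the space's frequency cutoff."""
    kept = [t for t in vocab.terms if t in space]
    return TermList(category=vocab.category, terms=kept)


# ---------------------------------------------------------------------------
# the orchestrated experiment
# ---------------------------------------------------------------------------


def _setting_key(setting: Setting) -> str:
    method, level = setting
    return method if level is None else f"{method}@{level}"


@dataclass
class EvaluationResult:
    """All fold-level records plus the aggregated statistics of one run.

    ``curves[setting]`` is a (folds × multiples) recall array;
    ``retrieved[setting]`` marks, per fold and vocabulary term, retrieval
    within the top ``profile_multiple``·n candidates; ``top_lists[setting]``
    stores the top-k candidate indices (into ``space_terms``) of every fold.
    Everything reported by :meth:`stats` and :meth:`to_dict` is recomputable
    from these records.
    """

    category: str
    vocab: Tuple[str, ...]
    excluded: Tuple[str, ...]
    V: int
    universe_size: int
    seed_size: int
    n_eval: int
    n_folds: int
    multiples: Tuple[int, ...]
    master_seed: int
    profile_multiple: int
    top_k: int
    settings: Tuple[Setting, ...]
    space_terms: Tuple[str, ...]
    folds: List[FoldSplit]
    curves: Dict[Setting, np.ndarray]
    retrieved: Dict[Setting, np.ndarray]
    top_lists: Dict[Setting, np.ndarray]
    eval_mask: np.ndarray
    baseline: Dict[int, Dict[str, float]]

    def fold_curves(self, setting: Setting) -> List[RecallCurve]:
        arr = self.curves[setting]
        return [
            RecallCurve(f, {m: float(arr[f, i]) for i, m in enumerate(self.multiples)})
            for f in range(self.n_folds)
        ]

    def stats(
        self, setting: Optional[Setting] = None
    ) -> Dict[int, Dict[str, float]]:
        if setting is None:
            raise ValueError("setting required; see .settings")
        arr = self.curves[setting]
        return {
            int(m): _stats_from_values(arr[:, i])
            for i, m in enumerate(self.multiples)
        }

    def mean_recall(self, setting: Setting, multiple: int) -> float:
        i = self.multiples.index(multiple)
        return float(self.curves[setting][:, i].mean())

    def best_setting(self, multiple: int) -> Setting:
        """Setting with the highest mean recall at the given multiple."""
        return max(
            self.settings,
            key=lambda s: (self.mean_recall(s, multiple), _setting_key(s)),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (setting, multiple)."""
        rows = []
        for setting in self.settings:
            for m, st in self.stats(setting).items():
                rows.append(
                    {
                        "method": setting[0],
                        "level": setting[1],
                        "multiple": m,
                        **st,
                        "baseline_recall": self.baseline[m]["recall"],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        best = self.best_setting(max(self.multiples))
        lines = [
            f"Category: {self.category}",
            f"Eligible vocabulary: {len(self.vocab)} terms "
            f"({len(self.excluded)} below cutoff), seed size {self.seed_size}, "
            f"n = {self.n_eval}, V = {self.V}, folds = {self.n_folds}",
            f"Best setting at top {max(self.multiples)}n: {_setting_key(best)} "
            f"(mean recall {self.mean_recall(best, max(self.multiples)):.3f}, "
            f"baseline {self.baseline[max(self.multiples)]['recall']:.3f})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        payload = {
            "category": self.category,
            "V": self.V,
            "universe_size": self.universe_size,
            "seed_size": self.seed_size,
            "n_eval": self.n_eval,
            "n_folds": self.n_folds,
            "multiples": list(self.multiples),
            "master_seed": self.master_seed,
            "profile_multiple": self.profile_multiple,
            "eligible_vocabulary": list(self.vocab),
            "excluded_below_cutoff": list(self.excluded),
            "baseline": {str(m): v for m, v in self.baseline.items()},
            "settings": {},
        }
        for setting in self.settings:
            payload["settings"][_setting_key(setting)] = {
                str(m): st for m, st in self.stats(setting).items()
            }
        best = self.best_setting(max(self.multiples))
        payload["best_setting"] = _setting_key(best)
        profile = retrieval_profile(self, best)
        payload["retrieval_profile"] = {
            "setting": _setting_key(best),
            "per_term": profile["per_term"],
            "histogram_bin_edges": profile["histogram_bin_edges"],
            "histogram_counts": profile["histogram_counts"],
            "never_evaluated": profile["never_evaluated"],
        }
        return payload


def evaluate_category(
    space: SemanticSpace,
    vocab: TermList,
    *,
    seed_size: int = 100,
    n_folds: int = 500,
    methods: Sequence[str] = ("cluster", "summed"),
    levels: Union[str, Sequence[int]] = "all",
    multiples: Sequence[int] = tuple(range(1, 11)),
    master_seed: int = 0,
    top_k: int = 100,
    profile_multiple: Optional[int] = None,
) -> EvaluationResult:
    """Run the full fold protocol for one category on one space.

    The vocabulary is first restricted to terms above the frequency cutoff;
    each fold clusters its seed draw, ranks the remaining units under every
    requested setting and measures recall of the held-out terms.
    """
    for m in methods:
        if m not in ("cluster", "summed", "random"):
            raise ConfigurationError(f"unknown method {m!r}")
    multiples = tuple(int(m) for m in sorted(multiples))
    if not multiples or multiples[0] < 1:
        raise ValueError("multiples must be positive integers")
    profile_multiple = profile_multiple or max(multiples)

    eligible = eligible_vocabulary(space, vocab)
    excluded = tuple(t for t in vocab.terms if t not in space)
    if len(eligible) <= seed_size:
        raise FoldError(
            f"{len(eligible)} eligible terms for category {vocab.category!r}; "
            f"need more than seed_size={seed_size}"
        )
    folds = make_folds(eligible, seed_size, n_folds, master_seed)
    n_eval = len(eligible) - seed_size

    if "cluster" in methods:
        if levels == "all":
            levels_list = list(range(1, seed_size + 1))
        else:
            levels_list = sorted({int(l) for l in levels})
            if any(l < 1 or l > seed_size for l in levels_list):
                raise ValueError("cluster levels must lie in 1..seed_size")
    else:
        levels_list = []

    settings: List[Setting] = [("cluster", L) for L in levels_list]
    if "summed" in methods:
        settings.append(("summed", None))
    if "random" in methods:
        settings.append(("random", None))

    space_terms = space.terms
    tindex = {t: i for i, t in enumerate(space_terms)}
    vindex = {t: i for i, t in enumerate(eligible.terms)}
    M = space.matrix.astype(np.float64)
    norms = np.linalg.norm(M, axis=1)
    if (norms == 0).any():
        zero = [space_terms[i] for i in np.nonzero(norms == 0)[0][:5]]
        raise ZeroVectorError(f"space contains zero vectors: {zero}")
    Un = M / norms[:, None]

    n_vocab = len(eligible.terms)
    top_k = min(top_k, space.V - seed_size)
    curves = {s: np.zeros((n_folds, len(multiples))) for s in settings}
    retrieved = {s: np.zeros((n_folds, n_vocab), dtype=bool) for s in settings}
    top_lists = {
        s: np.zeros((n_folds, top_k), dtype=np.int64) for s in settings
    }
    eval_mask = np.zeros((n_folds, n_vocab), dtype=bool)

    rand_children = np.random.SeedSequence([master_seed, 7]).spawn(n_folds)

    for f, fold in enumerate(folds):
        seed_rows = np.array([tindex[t] for t in fold.seed_terms], dtype=np.int64)
        is_cand = np.ones(len(space_terms), dtype=bool)
        is_cand[seed_rows] = False
        cand_rows = np.nonzero(is_cand)[0]  # ascending == lexicographic order
        Ucand = Un[cand_rows]
        eval_rows = np.array([tindex[t] for t in fold.eval_terms], dtype=np.int64)
        eval_pos = np.searchsorted(cand_rows, eval_rows)
        eval_vidx = np.array([vindex[t] for t in fold.eval_terms], dtype=np.int64)
        eval_mask[f, eval_vidx] = True
        n = len(fold.eval_terms)

        def record(setting: Setting, scores: np.ndarray) -> None:
            order = np.argsort(-scores, kind="stable")
            rank_of = np.empty(len(order), dtype=np.int64)
            rank_of[order] = np.arange(len(order))
            eval_ranks = rank_of[eval_pos]
            for i, m in enumerate(multiples):
                curves[setting][f, i] = np.count_nonzero(eval_ranks < m * n) / n
            retrieved[setting][f, eval_vidx] = eval_ranks < profile_multiple * n
            top_lists[setting][f] = cand_rows[order[:top_k]]

        if levels_list:
            seedset = SeedSet(vocab.category, fold.seed_terms)
            root = agglomerate(seedset, space)
            nodes = collect_nodes(root)
            node_col = {id(node): i for i, node in enumerate(nodes)}
            C = np.stack([node.centroid for node in nodes])
            Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
            cos_nodes = Ucand @ Cn.T
            for L in levels_list:
                part = cut_by_max_size(root, L)
                cols = [node_col[id(c)] for c in part.clusters]
                record(("cluster", L), cos_nodes[:, cols].max(axis=1))
        if "summed" in methods:
            record(("summed", None), Ucand @ Un[seed_rows].sum(axis=0))
        if "random" in methods:
            rng = np.random.default_rng(rand_children[f])
            record(("random", None), rng.random(len(cand_rows)))

    return EvaluationResult(
        category=vocab.category,
        vocab=tuple(eligible.terms),
        excluded=excluded,
        V=space.V,
        universe_size=space.V - seed_size,
        seed_size=seed_size,
        n_eval=n_eval,
        n_folds=n_folds,
        multiples=multiples,
        master_seed=master_seed,
        profile_multiple=profile_multiple,
        top_k=top_k,
        settings=tuple(settings),
        space_terms=space_terms,
        folds=folds,
        curves=curves,
        retrieved=retrieved,
        top_lists=top_lists,
        eval_mask=eval_mask,
        baseline=random_baseline(n_eval, space.V, multiples),
    )


def retrieval_profile(
    result: EvaluationResult,
    setting: Setting,
    frequencies: Optional[Mapping[str, int]] = None,
    freq_bin_edges: Sequence[float] = (0, 10, 20, 50, 100, 200, 500, 1000, math.inf),
) -> dict:
    """Per-term retrieval proportions with 5 % histogram binning.

    For every vocabulary term: the share of folds in which it was retrieved
    within the top ``profile_multiple``·n candidates when it sat in the
    evaluation set.  Terms never drawn into any evaluation set are excluded
    and listed separately.  When ``frequencies`` is given, the <5 % and >95 %
    groups are cross-tabulated against corpus-frequency bins.
    """
    appearances = result.eval_mask.sum(axis=0)
    hits = (result.retrieved[setting] & result.eval_mask).sum(axis=0)
    per_term = []
    proportions = []
    low_terms, high_terms, never = [], [], []
    for i, term in enumerate(result.vocab):
        if appearances[i] == 0:
            never.append(term)
            continue
        prop = float(hits[i]) / float(appearances[i])
        proportions.append(prop)
        per_term.append(
            {
                "term": term,
                "appearances": int(appearances[i]),
                "retrieved": int(hits[i]),
                "proportion": prop,
            }
        )
        if prop < 0.05:
            low_terms.append(term)
        elif prop > 0.95:
            high_terms.append(term)

    edges = np.linspace(0.0, 1.0, 21)  # 5 % bins
    hist, _ = np.histogram(proportions, bins=edges)
    out = {
        "setting": _setting_key(setting),
        "per_term": per_term,
        "histogram_bin_edges": [float(e) for e in edges],
        "histogram_counts": [int(c) for c in hist],
        "low_terms": low_terms,
        "high_terms": high_terms,
        "never_evaluated": never,
    }
    if frequencies is not None:
        fedges = list(freq_bin_edges)
        labels = [
            f"{int(a)}-{int(b) if math.isfinite(b) else 'inf'}"
            for a, b in zip(fedges, fedges[1:])
        ]
        crosstab = {label: {"low": 0, "high": 0} for label in labels}
        for group, terms in (("low", low_terms), ("high", high_terms)):
            for term in terms:
                freq = frequencies.get(term, 0)
                for label, a, b in zip(labels, fedges, fedges[1:]):
                    if a < freq <= b:
                        crosstab[label][group] += 1
                        break
        out["frequency_crosstab"] = crosstab
    return out


def unique_top_candidates(
    result: EvaluationResult,
    setting: Setting,
    top_k: Optional[int] = None,
    known_vocab: Optional[Union[TermList, Iterable[str]]] = None,
) -> dict:
    """Concatenate every fold's top-k candidates and deduplicate.

    Returns the unique terms in first-seen order, their count, and — when a
    known vocabulary is supplied — the list and count after removing terms
    already present in it.
    """
    lists = result.top_lists[setting]
    k = lists.shape[1] if top_k is None else min(top_k, lists.shape[1])
    seen: Dict[str, None] = {}
    for f in range(lists.shape[0]):
        for idx in lists[f, :k]:
            term = result.space_terms[idx]
            if term not in seen:
                seen[term] = None
    unique_terms = list(seen)
    out = {
        "n_items": int(lists.shape[0] * k),
        "unique_terms": unique_terms,
        "n_unique": len(unique_terms),
    }
    if known_vocab is not None:
        known = set(known_vocab.terms if isinstance(known_vocab, TermList) else known_vocab)
        filtered = [t for t in unique_terms if t not in known]
        out["unique_terms_not_in_vocab"] = filtered
        out["n_unique_not_in_vocab"] = len(filtered)
    return out
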
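"""The package's built-in synthetic benchmark.

A single set of reference study conditions — the default synthetic corpus
(three planted categories of 150 vocabulary terms each, mixing rate 0.05,
roughly 100k tokens) evaluated with a 2000-dimensional, window 1+1
direction-vector space, frequency cutoff 5, seed sets of 45 terms and 100
bootstrap folds — plus helpers to run the mixing-rate degradation sweep and
the random-score calibration.  Both the test suite and the reproduction
script drive the pipeline through these helpers so the reported numbers come
from one place.

The seed-set size and the vocabulary Zipf exponent follow from the design
arithmetic: the strong-signal corpus should allow near-complete recall at
top 10n while the random baseline 10n/V stays an order of magnitude below
it, which requires n ≲ V/100 ≈ 25 held-out terms per fold.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import EvaluationResult, evaluate_category
from .preprocess import preprocess_corpus
from .semantic_space import SemanticSpace, SpaceConfig, build_space
from .synthdata import SynthConfig, SynthCorpus, generate_sentences

__all__ = [
    "REFERENCE_ALPHA",
    "ALPHA_GRID",
    "reference_synth_config",
    "reference_space_config",
    "EVAL_PARAMS",
    "build_reference_space",
    "evaluate_reference",
    "mixing_sweep",
]

REFERENCE_ALPHA = 0.05
ALPHA_GRID: Tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 1.0)
PRESET = "content-lemma"

EVAL_PARAMS = dict(seed_size=45, n_folds=100, multiples=tuple(range(1, 11)))


def reference_synth_config(seed: int, alpha: float = REFERENCE_ALPHA) -> SynthConfig:
    """Default generator conditions at the given mixing rate."""
    return SynthConfig(rng_seed=seed, mixing_rate=alpha)


def reference_space_config(seed: int) -> SpaceConfig:
    return SpaceConfig(
        dimensionality=2000,
        nonzeros=10,
        window=1,
        use_permutation=True,
        min_frequency=5,
        master_seed=seed,
    )


def build_reference_space(
    seed: int, alpha: float = REFERENCE_ALPHA
) -> Tuple[SynthCorpus, SemanticSpace]:
    """Generate the benchmark corpus at ``alpha`` and build its space."""
    corpus = generate_sentences(reference_synth_config(seed, alpha))
    units = preprocess_corpus(corpus.sentences, PRESET)
    space = build_space(units, reference_space_config(seed + 1))
    return corpus, space


def evaluate_reference(
    corpus: SynthCorpus,
    space: SemanticSpace,
    category: str = "category-0",
    seed: int = 0,
    methods: Sequence[str] = ("cluster", "summed"),
) -> EvaluationResult:
    return evaluate_category(
        space,
        corpus.term_lists[category],
        methods=methods,
        master_seed=seed + 2,
        **EVAL_PARAMS,
    )


def mixing_sweep(
    seed: int, alphas: Sequence[float] = ALPHA_GRID, category: str = "category-0"
) -> Dict[float, EvaluationResult]:
    """Evaluate one category across the mixing-rate grid.

    All corpora share the generator seed, so they differ only in the slots
    whose mixing draw separates the α values.
    """
    out: Dict[float, EvaluationResult] = {}
    for alpha in alphas:
        corpus, space = build_reference_space(seed, alpha)
        out[alpha] = evaluate_reference(corpus, space, category, seed)
    return out
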
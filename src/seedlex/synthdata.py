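"""Synthetic corpora with planted distributional category structure.

The generator emulates the situation the pipeline targets: a large corpus of
short, tagged sentences in which terms of each planted semantic category
co-occur preferentially with a category-specific inventory of context words
(the distributional signal the method exploits), on top of a background
vocabulary, with Zipf-shaped term frequencies that span the frequency cutoff.

Each sentence has a *topic* — one of the categories or background.  Category
sentences contain one to three vocabulary-term slots; every remaining slot is
a context slot filled from the topic's inventory.  With probability ``α``
(``mixing_rate``) any slot is instead filled by a uniform draw from the
global lexicon.  At ``α = 0`` category contexts are perfectly separated; at
``α = 1`` every slot of every sentence is an exchangeable uniform draw, so
the category label carries no information and retrieval can do no better
than chance.  Case particles and inflected verbs (with lemmas) are
interleaved so both pre-processing presets are exercised.

All randomness is split over three independent streams (structure, mixing,
pool) so that corpora generated at different ``α`` from the same seed share
every other random decision — they differ only in the slots whose mixing
draw falls between the two α values.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import (
    Sentence,
    TermList,
    Token,
    write_tagged_corpus,
    write_term_list,
)

__all__ = ["SynthConfig", "SynthCorpus", "generate_sentences", "generate", "degrade"]

_PARTICLES = ("を", "が", "に", "で")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic corpus.

    Defaults give three categories of 150 vocabulary terms whose Zipf-shaped
    frequencies straddle a cutoff of a few occurrences, ~100k tokens, and a
    background vocabulary large enough that a random candidate list is a weak
    baseline.  ``mixing_rate`` is the probability that a slot is filled from
    the global lexicon instead of its topic's own inventory.
    """

    categories: int = 3
    vocab_terms_per_category: int = 150
    context_words_per_category: int = 40
    verbs_per_category: int = 12  # of the context inventory
    background_vocab: int = 3000
    sentences: int = 12000
    sentence_length: Tuple[int, int] = (4, 10)
    mixing_rate: float = 0.05
    vocab_zipf: float = 1.5
    background_zipf: float = 0.5
    background_fraction: float = 0.35
    particle_rate: float = 0.25
    confound: bool = False
    confound_terms: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_rate <= 1.0:
            raise ValueError("mixing_rate must lie in [0, 1]")
        if self.categories < 1 or self.vocab_terms_per_category < 2:
            raise ValueError("need at least one category with two terms")
        if self.verbs_per_category > self.context_words_per_category:
            raise ValueError("verbs_per_category exceeds the context inventory")
        lo, hi = self.sentence_length
        if lo < 1 or hi < lo:
            raise ValueError("invalid sentence_length range")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")


@dataclass
class SynthCorpus:
    """In-memory generated corpus plus its ground-truth manifest."""

    config: SynthConfig
    sentences: List[Sentence]
    term_lists: Dict[str, TermList]
    manifest: dict


def _zipf_cumulative(n: int, exponent: float) -> np.ndarray:
    weights = np.arange(1, n + 1, dtype=np.float64) ** (-exponent)
    cum = np.cumsum(weights)
    return cum / cum[-1]


def _category_name(c: int) -> str:
    return f"category-{c}"


def generate_sentences(config: SynthConfig) -> SynthCorpus:
    """Generate the corpus in memory; deterministic in ``config.rng_seed``."""
    c_count = config.categories
    struct_ss, pool_ss, mix_ss = np.random.SeedSequence(config.rng_seed).spawn(3)
    rs = np.random.default_rng(struct_ss)
    rpool = np.random.default_rng(pool_ss)
    rmix = np.random.default_rng(mix_ss)

    vocab: List[List[Token]] = []
    inventories: List[List[Token]] = []
    for c in range(c_count):
        vocab.append(
            [
                Token(f"語{c}t{i:03d}", "noun")
                for i in range(config.vocab_terms_per_category)
            ]
        )
        inv: List[Token] = [
            Token(f"文{c}x{j:02d}", "noun")
            for j in range(config.context_words_per_category - config.verbs_per_category)
        ]
        inv += [
            Token(f"動{c}v{j:02d}た", "verb", f"動{c}v{j:02d}")
            for j in range(config.verbs_per_category)
        ]
        inventories.append(inv)
    background = [Token(f"背{j:04d}", "noun") for j in range(config.background_vocab)]
    particles = [Token(p, "case-particle") for p in _PARTICLES]

    lexicon: List[Token] = [t for group in vocab for t in group]
    lexicon += [t for inv in inventories for t in inv]
    lexicon += background

    home: Dict[str, str] = {}
    for c in range(c_count):
        for t in vocab[c]:
            home[t.surface] = _category_name(c)
        for t in inventories[c]:
            home[t.surface] = _category_name(c)
    for t in background:
        home[t.surface] = "background"

    cum_vocab = _zipf_cumulative(config.vocab_terms_per_category, config.vocab_zipf)
    cum_bg = _zipf_cumulative(config.background_vocab, config.background_zipf)
    inv_size = config.context_words_per_category

    n_sent = config.sentences
    lo, hi = config.sentence_length
    is_background = rs.random(n_sent) < config.background_fraction
    topics = rs.integers(0, c_count, size=n_sent)
    lengths = rs.integers(lo, hi + 1, size=n_sent)
    kterms = rs.integers(1, 4, size=n_sent)
    total_slots = int(lengths.sum())
    own_u = rs.random(total_slots)
    particle_u = rs.random(total_slots)
    particle_id = rs.integers(0, len(_PARTICLES), size=total_slots)
    pool_idx = rpool.integers(0, len(lexicon), size=total_slots)
    mix_u = rmix.random(total_slots)

    alpha = config.mixing_rate
    topic_labels = [_category_name(c) for c in range(c_count)] + ["background"]
    crosstab = {t: Counter() for t in topic_labels}

    sentences: List[Sentence] = []
    ptr = 0
    for s in range(n_sent):
        length = int(lengths[s])
        if is_background[s]:
            topic_label = "background"
            slot_is_term = np.zeros(length, dtype=bool)
        else:
            topic = int(topics[s])
            topic_label = _category_name(topic)
            kt = min(int(kterms[s]), length)
            slot_is_term = np.zeros(length, dtype=bool)
            slot_is_term[:kt] = True
            rs.shuffle(slot_is_term)
        sent: Sentence = []
        for pos in range(length):
            u = own_u[ptr]
            if slot_is_term[pos]:
                idx = int(np.searchsorted(cum_vocab, u))
                token = vocab[topic][idx]
            elif is_background[s]:
                idx = int(np.searchsorted(cum_bg, u))
                token = background[idx]
            else:
                token = inventories[topic][int(u * inv_size)]
            if mix_u[ptr] < alpha:
                token = lexicon[int(pool_idx[ptr])]
            sent.append(token)
            if not slot_is_term[pos]:
                crosstab[topic_label][home[token.surface]] += 1
            if particle_u[ptr] < config.particle_rate:
                sent.append(particles[int(particle_id[ptr])])
            ptr += 1
        sentences.append(sent)

    confound_terms: List[str] = []
    if config.confound:
        # A group of non-vocabulary terms sharing one high-frequency context
        # verb with category 0 — a planted confound that should rank high.
        shared = inventories[0][-1]  # a category-0 verb
        confound_tokens = [
            Token(f"飲c{j:02d}", "noun") for j in range(config.confound_terms)
        ]
        confound_terms = [t.surface for t in confound_tokens]
        n_extra = max(1, config.sentences // 20)
        for _ in range(n_extra):
            length = int(rs.integers(lo, hi + 1))
            sent = []
            for pos in range(length):
                if rs.random() < 0.4:
                    sent.append(confound_tokens[int(rs.integers(0, len(confound_tokens)))])
                elif rs.random() < 0.5:
                    sent.append(shared)
                else:
                    sent.append(background[int(rs.integers(0, len(background)))])
            sentences.append(sent)

    term_lists = {
        _category_name(c): TermList(
            category=_category_name(c), terms=[t.surface for t in vocab[c]]
        )
        for c in range(c_count)
    }

    surface_counts = Counter(t.surface for sent in sentences for t in sent)
    manifest = {
        "config": dataclasses.asdict(config),
        "categories": {
            _category_name(c): {
                "terms": [t.surface for t in vocab[c]],
                "context_nouns": [
                    t.surface for t in inventories[c] if t.tag == "noun"
                ],
                "context_verbs": [
                    t.surface for t in inventories[c] if t.tag == "verb"
                ],
            }
            for c in range(c_count)
        },
        "background_terms": [t.surface for t in background],
        "confound_terms": confound_terms,
        "particles": list(_PARTICLES),
        "n_sentences": len(sentences),
        "n_tokens": int(sum(len(s) for s in sentences)),
        "surface_counts": dict(surface_counts),
        "context_source_crosstab": {
            topic: dict(counter) for topic, counter in crosstab.items()
        },
    }
    return SynthCorpus(config, sentences, term_lists, manifest)


def generate(config: SynthConfig, out_dir: str | Path) -> Dict[str, Path]:
    """Generate and write corpus, per-category term lists and manifest.

    Same seed → byte-identical output files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus = generate_sentences(config)
    paths: Dict[str, Path] = {"corpus": out_dir / "corpus.txt"}
    write_tagged_corpus(corpus.sentences, paths["corpus"])
    for name, term_list in corpus.term_lists.items():
        path = out_dir / f"vocab_{name}.txt"
        write_term_list(term_list, path)
        paths[f"vocab:{name}"] = path
    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(corpus.manifest, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
    return paths


def degrade(
    config: SynthConfig, alpha_grid: Sequence[float]
) -> List[SynthCorpus]:
    """One corpus per mixing rate, all other randomness shared.

    The grid must be ascending in [0, 1]; two grid corpora differ only in
    the slots whose mixing draw separates their α values.
    """
    grid = list(alpha_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("alpha_grid must be ascending")
    if any(not 0.0 <= a <= 1.0 for a in grid):
        raise ValueError("alpha values must lie in [0, 1]")
    return [
        generate_sentences(dataclasses.replace(config, mixing_rate=a)) for a in grid
    ]
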
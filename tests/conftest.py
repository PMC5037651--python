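import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seedlex as sx

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_SYNTH_SEED = 101


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-structure corpus with a matching semantic space.

    Strong category signal (mixing rate 0.05) at a scale where the whole
    pipeline runs in seconds; used by ranking/evaluation tests.
    """
    config = sx.SynthConfig(
        vocab_terms_per_category=40,
        context_words_per_category=16,
        verbs_per_category=5,
        background_vocab=400,
        sentences=2500,
        rng_seed=SMALL_SYNTH_SEED,
    )
    corpus = sx.generate_sentences(config)
    units = list(sx.preprocess_corpus(corpus.sentences, "content-lemma"))
    space = sx.build_space(
        units,
        sx.SpaceConfig(
            dimensionality=512,
            nonzeros=8,
            window=1,
            min_frequency=3,
            master_seed=SMALL_SYNTH_SEED + 1,
        ),
    )
    return corpus, space


@pytest.fixture(scope="session")
def small_eval(small_synth):
    """Fold evaluation of category-0 on the small corpus (both methods)."""
    corpus, space = small_synth
    result = sx.evaluate_category(
        space,
        corpus.term_lists["category-0"],
        seed_size=15,
        n_folds=25,
        master_seed=SMALL_SYNTH_SEED + 2,
    )
    return corpus, space, result


@pytest.fixture
def tagged_corpus_file(tmp_path):
    """A hand-written tagged corpus exercising lemmas, particles, widths."""
    lines = [
        "薬/noun/薬 を/case-particle 飲んだ/verb/飲む",
        "",
        "ｶﾞﾝ/noun が/case-particle 痛い/verbal-adjective/痛い (^_^)/other",
        "hello/other world/other",
        "頭/noun が/case-particle 痛い/verbal-adjective/痛い",
    ]
    path = tmp_path / "corpus.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
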
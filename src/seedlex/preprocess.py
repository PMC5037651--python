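"""Text normalisation and the token-filtering presets.

Morphological analysis happens upstream; this module only implements the
selection and lemmatisation rules applied to an already tagged corpus:

* half-width katakana → full-width normalisation,
* removal of emoticons and of sentences consisting solely of Latin
  characters, digits and ASCII punctuation,
* a declarative tag → action filter (``drop`` / ``keep-surface`` /
  ``keep-lemma``) with the two shipped presets used to build the two corpus
  versions fed to the semantic space:

  - ``content-lemma``: keep nouns/pronouns/adjectival nouns as surface forms,
    lemmatise verbs and verbal/adverbial adjectives, drop everything else
    (case particles included).
  - ``particles-inflections``: as above but verbs and verbal adjectives keep
    their inflected surface, and case particles plus polarity/mood/voice
    inflection units are retained.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

from .corpus_io import Sentence, Token

__all__ = [
    "DROP",
    "KEEP_SURFACE",
    "KEEP_LEMMA",
    "FilterPolicy",
    "CONTENT_LEMMA",
    "PARTICLES_INFLECTIONS",
    "get_preset",
    "normalize_width",
    "strip_nonlinguistic",
    "apply_filter",
    "preprocess_corpus",
    "DEFAULT_SMILEY_PATTERNS",
]

DROP = "drop"
KEEP_SURFACE = "keep-surface"
KEEP_LEMMA = "keep-lemma"
_ACTIONS = (DROP, KEEP_SURFACE, KEEP_LEMMA)


@dataclass(frozen=True)
class FilterPolicy:
    """Mapping from tag to action; unknown tags fall back to ``default``."""

    actions: Dict[str, str]
    default: str = DROP
    name: Optional[str] = None

    def __post_init__(self) -> None:
        for tag, action in self.actions.items():
            if action not in _ACTIONS:
                raise ValueError(f"unknown action {action!r} for tag {tag!r}")
        if self.default not in _ACTIONS:
            raise ValueError(f"unknown default action {self.default!r}")

    def action_for(self, tag: str) -> str:
        return self.actions.get(tag, self.default)


CONTENT_LEMMA = FilterPolicy(
    actions={
        "noun": KEEP_SURFACE,
        "pronoun": KEEP_SURFACE,
        "adjectival-noun": KEEP_SURFACE,
        "verb": KEEP_LEMMA,
        "verbal-adjective": KEEP_LEMMA,
        "adverbial-adjective": KEEP_LEMMA,
    },
    name="content-lemma",
)

PARTICLES_INFLECTIONS = FilterPolicy(
    actions={
        "noun": KEEP_SURFACE,
        "pronoun": KEEP_SURFACE,
        "adjectival-noun": KEEP_SURFACE,
        "verb": KEEP_SURFACE,
        "verbal-adjective": KEEP_SURFACE,
        "adverbial-adjective": KEEP_LEMMA,
        "case-particle": KEEP_SURFACE,
        "inflection-polarity": KEEP_SURFACE,
        "inflection-mood": KEEP_SURFACE,
        "inflection-voice": KEEP_SURFACE,
    },
    name="particles-inflections",
)

_PRESETS = {
    "content-lemma": CONTENT_LEMMA,
    "particles-inflections": PARTICLES_INFLECTIONS,
}


def get_preset(name: str) -> FilterPolicy:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# width normalisation
# ---------------------------------------------------------------------------

# Half-width katakana block (U+FF66..U+FF9F, including the voicing marks).
# NFKC maps each run to full-width forms and composes base + voicing mark
# into the precomposed code point.  Only these code points are touched.
_HALFWIDTH_KANA = re.compile("[ｦ-ﾟ]+")


def _widen(text: str) -> str:
    return _HALFWIDTH_KANA.sub(
        lambda m: unicodedata.normalize("NFKC", m.group(0)), text
    )


def normalize_width(sentence: Sentence) -> Sentence:
    """Replace half-width katakana with full-width equivalents (idempotent)."""
    out: Sentence = []
    for tok in sentence:
        surface = _widen(tok.surface)
        lemma = _widen(tok.lemma) if tok.lemma is not None else None
        if surface == tok.surface and lemma == tok.lemma:
            out.append(tok)
        else:
            out.append(Token(surface, tok.tag, lemma))
    return out


# ---------------------------------------------------------------------------
# non-linguistic material
# ---------------------------------------------------------------------------

#: Default emoticon inventory, applied token-wise.  User-extensible; no claim
#: of completeness is made — the list covers the common ASCII/kaomoji shapes.
DEFAULT_SMILEY_PATTERNS: Sequence[str] = (
    # parenthesised kaomoji: (^_^) (;_;) (T_T) (^o^;) (*´ω`*) ...
    r"^[\(（][\^;；:ToOｏﾟдДωθ\-_~～・\.。'`´\*=\+<>vV┬┴ー…\s]{1,12}[\)）]$",
    # bare carets: ^^ ^_^ ^^;
    r"^\^[_\-\^]*\^;*$",
    r"^orz$",
    r"^[;；T]_[;；T]$",
)

_LATIN_ONLY = re.compile(r"^[\x21-\x7E]+$")  # ASCII letters, digits, punctuation


def strip_nonlinguistic(
    sentences: Iterable[Sentence],
    smiley_patterns: Optional[Sequence[str]] = None,
) -> Iterator[Sentence]:
    """Drop emoticon tokens and Latin-only sentences.

    A sentence whose every surface consists solely of Latin letters, digits
    and ASCII punctuation is removed entirely; tokens matching one of the
    smiley patterns are removed; a sentence left empty is dropped.
    """
    patterns = [re.compile(p) for p in (smiley_patterns or DEFAULT_SMILEY_PATTERNS)]
    for sent in sentences:
        if sent and all(_LATIN_ONLY.match(tok.surface) for tok in sent):
            continue
        kept = [
            tok for tok in sent if not any(p.match(tok.surface) for p in patterns)
        ]
        if kept:
            yield kept


# ---------------------------------------------------------------------------
# tag filtering
# ---------------------------------------------------------------------------


def apply_filter(
    sentences: Iterable[Sentence],
    policy: FilterPolicy,
    counters: Optional[Dict[str, int]] = None,
) -> Iterator[List[str]]:
    """Reduce tagged sentences to the surviving semantic units.

    Each surviving token contributes its surface or lemma according to the
    policy; token order is preserved and sentences left empty are dropped.
    A ``keep-lemma`` action on a token without a lemma falls back to the
    surface and increments ``counters['missing_lemma']``.
    """
    for sent in sentences:
        units: List[str] = []
        for tok in sent:
            action = policy.action_for(tok.tag)
            if action == DROP:
                continue
            if action == KEEP_LEMMA:
                if tok.lemma is None:
                    if counters is not None:
                        counters["missing_lemma"] = counters.get("missing_lemma", 0) + 1
                    units.append(tok.surface)
                else:
                    units.append(tok.lemma)
            else:
                units.append(tok.surface)
        if units:
            yield units


def preprocess_corpus(
    sentences: Iterable[Sentence],
    policy: FilterPolicy | str,
    smiley_patterns: Optional[Sequence[str]] = None,
    counters: Optional[Dict[str, int]] = None,
) -> Iterator[List[str]]:
    """Full pipeline: width normalisation → strip non-linguistic → filter."""
    if isinstance(policy, str):
        policy = get_preset(policy)
    normalized = (normalize_width(s) for s in sentences)
    cleaned = strip_nonlinguistic(normalized, smiley_patterns)
    return apply_filter(cleaned, policy, counters)
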
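"""Readers and writers for the on-disk formats used by the pipeline.

The pipeline consumes a *tagged corpus* produced upstream by a morphological
analyser: one sentence per line, tokens separated by single spaces, each token
written as ``surface/tag`` or ``surface/tag/lemma``.  A literal ``/`` inside a
field is escaped by doubling it (``//``).  Files are UTF-8 without BOM.

Term lists are plain text, one term per line.  Ranked candidate lists are TSV
(``rank<TAB>term<TAB>score``, scores printed with six decimals) and evaluation
reports are JSON documents; both round-trip exactly at the serialised
precision through the matching readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, List, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .ranking import RankedCandidateList

__all__ = [
    "Token",
    "Sentence",
    "TermList",
    "CorpusIOError",
    "CorpusParseError",
    "CorpusEncodingError",
    "EmptyVocabularyError",
    "read_tagged_corpus",
    "write_tagged_corpus",
    "read_term_list",
    "write_term_list",
    "write_candidates",
    "read_candidates",
    "write_report",
    "read_report",
]

SCORE_DECIMALS = 6


class CorpusIOError(Exception):
    """Base class for corpus/term-list I/O failures."""


class CorpusParseError(CorpusIOError):
    """A line of a tagged corpus could not be parsed."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CorpusEncodingError(CorpusIOError):
    """A corpus file contained bytes that are not valid UTF-8."""


class EmptyVocabularyError(CorpusIOError):
    """A term-list file yielded no terms."""


@dataclass(frozen=True)
class Token:
    """One semantic unit of a segmented sentence.

    ``tag`` comes from an open inventory (``noun``, ``verb``,
    ``case-particle``, ``inflection-polarity`` ...); ``lemma`` is present only
    when the upstream analyser provides one.
    """

    surface: str
    tag: str
    lemma: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surface or any(ch.isspace() for ch in self.surface):
            raise ValueError(f"invalid token surface: {self.surface!r}")
        if not self.tag or any(ch.isspace() for ch in self.tag):
            raise ValueError(f"invalid token tag: {self.tag!r}")
        if self.lemma is not None and not self.lemma:
            raise ValueError("lemma, when present, must be non-empty")


#: A sentence is an ordered list of tokens; order is preserved exactly as read.
Sentence = List[Token]


@dataclass
class TermList:
    """An ordered, duplicate-free list of vocabulary terms for one category."""

    category: str
    terms: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if not t or any(ch.isspace() for ch in t):
                raise ValueError(f"invalid term: {t!r}")
            if t in seen:
                raise ValueError(f"duplicate term: {t!r}")
            seen.add(t)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms


# ---------------------------------------------------------------------------
# tagged corpus dialect
# ---------------------------------------------------------------------------

_ESC = "\x00"  # sentinel for the doubled-slash escape; never valid in text


def _escape_field(text: str) -> str:
    return text.replace("/", "//")


def _split_token_fields(token: str) -> List[str]:
    return [p.replace(_ESC, "/") for p in token.replace("//", _ESC).split("/")]


def format_token(token: Token) -> str:
    """Serialise a token in the ``surface/tag[/lemma]`` dialect."""
    parts = [_escape_field(token.surface), _escape_field(token.tag)]
    if token.lemma is not None:
        parts.append(_escape_field(token.lemma))
    return "/".join(parts)


def parse_token(text: str, line: Optional[int] = None) -> Token:
    fields = _split_token_fields(text)
    if len(fields) == 2:
        surface, tag = fields
        lemma = None
    elif len(fields) == 3:
        surface, tag, lemma = fields
    else:
        raise CorpusParseError(
            f"token {text!r} has {len(fields)} fields (expected 2 or 3)", line
        )
    try:
        return Token(surface, tag, lemma)
    except ValueError as exc:
        raise CorpusParseError(str(exc), line) from exc


def read_tagged_corpus(path: str | Path) -> Iterator[Sentence]:
    """Yield sentences from a tagged-corpus file in file order.

    Blank lines yield no sentence.  Malformed tokens raise
    :class:`CorpusParseError` naming the offending line; undecodable bytes
    raise :class:`CorpusEncodingError`.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        for lineno, raw in enumerate(fh, start=1):
            try:
                line = raw.decode("utf-8")
            except UnicodeDecodeError as exc:
                raise CorpusEncodingError(
                    f"{path}: line {lineno} is not valid UTF-8"
                ) from exc
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            yield [parse_token(tok, lineno) for tok in line.split(" ") if tok]


def write_tagged_corpus(sentences: Iterable[Sentence], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sent in sentences:
            fh.write(" ".join(format_token(t) for t in sent))
            fh.write("\n")


# ---------------------------------------------------------------------------
# term lists
# ---------------------------------------------------------------------------


def read_term_list(path: str | Path, category: str) -> TermList:
    """Read a one-term-per-line UTF-8 file.

    Surrounding whitespace is stripped, empty lines dropped, and duplicates
    collapsed to the first occurrence.  A file with no surviving terms raises
    :class:`EmptyVocabularyError`.
    """
    path = Path(path)
    terms: List[str] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.strip()
            if not term or term in seen:
                continue
            seen.add(term)
            terms.append(term)
    if not terms:
        raise EmptyVocabularyError(f"{path}: no terms found")
    return TermList(category=category, terms=terms)


def write_term_list(term_list: TermList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in term_list.terms:
            fh.write(term + "\n")


# ---------------------------------------------------------------------------
# ranked candidate lists (TSV)
# ---------------------------------------------------------------------------


def write_candidates(candidates: "RankedCandidateList", path: str | Path) -> None:
    """Write a ranked candidate list as TSV.

    The first line is a comment carrying the ranking method and cluster level,
    the second the column header; each data row is ``rank<TAB>term<TAB>score``
    with the score at six decimals.
    """
    path = Path(path)
    level = "" if candidates.level is None else str(candidates.level)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# method={candidates.method}\tlevel={level}\n")
        fh.write("rank\tterm\tscore\n")
        for rank, (term, score) in enumerate(candidates.entries, start=1):
            fh.write(f"{rank}\t{term}\t{score:.{SCORE_DECIMALS}f}\n")


def read_candidates(path: str | Path) -> "RankedCandidateList":
    from .ranking import RankedCandidateList

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# method="):
            raise CorpusParseError(f"{path}: missing candidate-list header", 1)
        fields = dict(
            part.split("=", 1) for part in header[2:].split("\t") if "=" in part
        )
        method = fields.get("method", "cluster")
        level = int(fields["level"]) if fields.get("level") else None
        columns = fh.readline().rstrip("\n").split("\t")
        if columns != ["rank", "term", "score"]:
            raise CorpusParseError(f"{path}: unexpected columns {columns}", 2)
        entries = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusParseError(f"bad candidate row {line!r}", lineno)
            entries.append((parts[1], float(parts[2])))
    return RankedCandidateList(method=method, level=level, entries=tuple(entries))


# ---------------------------------------------------------------------------
# evaluation reports (JSON)
# ---------------------------------------------------------------------------


def write_report(summary, path: str | Path) -> None:
    """Write an evaluation report (or any JSON-safe mapping) to ``path``.

    Objects exposing ``to_dict()`` are serialised through it.  Keys are sorted
    so identical summaries produce byte-identical files; floats round-trip
    exactly through :func:`read_report`.
    """
    obj = summary.to_dict() if hasattr(summary, "to_dict") else summary
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
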
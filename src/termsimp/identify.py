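"""Difficult-term identification: tokenize, tag, and flag unfamiliar words.

This is the first algorithm step: every word token in the document is looked
up in the background frequency table and flagged when its corpus count falls
strictly below the familiarity threshold.  Tokenization is deliberately
simple and fully deterministic — offsets into the original document are kept
on every token so downstream modules (worksheet blanking, verification) can
reconstruct text byte-exactly.

Sentence splitting rule: a terminal punctuation mark in ``. ! ?`` ends a
sentence when it is followed by whitespace and an uppercase letter (an
optional opening quote or bracket may intervene) and, for a period, the
preceding word is not a known abbreviation.  The abbreviation list is
configurable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, runtime_checkable

from termsimp.lexicon import (
    DEFAULT_EXEMPTIONS,
    ExemptionPolicy,
    FrequencyTable,
    normalize_term,
)

log = logging.getLogger(__name__)

# words (letters/digits, internal hyphen/apostrophe kept) or single non-space chars
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’\-][^\W_]+)*|\S", re.UNICODE)
_BOUNDARY_FOLLOW_RE = re.compile(r"\s+[\"'“‘(\[]?[A-Z]")

DEFAULT_ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "prof", "st", "vs", "etc", "e.g", "i.e", "eg", "ie", "fig", "no", "al"}
)

COARSE_FALLBACK = "other"

#: fine tag -> coarse tag collapse used for Penn-style taggers
PENN_TO_COARSE = {
    **{t: "noun" for t in ("NN", "NNS", "NNP", "NNPS")},
    **{t: "verb" for t in ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD")},
    **{t: "adj" for t in ("JJ", "JJR", "JJS")},
    **{t: "adv" for t in ("RB", "RBR", "RBS")},
}


@dataclass
class Token:
    """One token with its provenance in the source document.

    ``char_span`` is 0-based, half-open; slicing the document at it yields
    ``surface`` exactly.
    """

    surface: str
    normalized: str
    sentence_index: int
    token_index: int
    char_span: tuple[int, int]
    pos: str = COARSE_FALLBACK

    @property
    def is_word(self) -> bool:
        return any(c.isalnum() for c in self.surface)


@dataclass
class DifficultTerm:
    """A flagged token together with its corpus frequency."""

    token: Token
    frequency: int


@runtime_checkable
class Tagger(Protocol):
    """Contract for part-of-speech taggers: one coarse tag per surface form."""

    def tag(self, surface: str, normalized: str) -> str: ...


class DictionaryTagger:
    """Tagger backed by a plain ``word -> coarse tag`` mapping.

    Unknown words fall back to ``other``.  Used for fixtures and for
    deployments where a tagged lexicon is available.
    """

    def __init__(self, mapping: Mapping[str, str], fallback: str = COARSE_FALLBACK):
        self._mapping = {normalize_term(k): v for k, v in mapping.items()}
        self._fallback = fallback

    def tag(self, surface: str, normalized: str) -> str:
        return self._mapping.get(normalized, self._fallback)


# closed-class words never worth tagging as content words
_FUNCTION_WORDS = frozenset(
    """a an the and or but if of in on at to for from by with as is are was were be been
    being am do does did have has had this that these those it its he she they we you i
    his her their our your not no nor so than then there here when while which who whom
    whose what why how""".split()
)

_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ly", "adv"),
    ("tion", "noun"), ("sion", "noun"), ("ment", "noun"), ("ness", "noun"),
    ("ity", "noun"), ("ism", "noun"), ("itis", "noun"), ("osis", "noun"), ("logy", "noun"),
    ("ize", "verb"), ("izes", "verb"), ("ized", "verb"), ("izing", "verb"),
    ("ise", "verb"), ("ate", "verb"), ("ates", "verb"), ("fy", "verb"),
    ("ing", "verb"), ("ed", "verb"),
    ("ous", "adj"), ("ful", "adj"), ("ive", "adj"), ("ic", "adj"), ("ical", "adj"),
    ("al", "adj"), ("able", "adj"), ("ible", "adj"), ("less", "adj"),
)


class HeuristicTagger:
    """Suffix-rule tagger for use when no tagged lexicon is supplied.

    Function words tag ``other``; otherwise the first matching suffix rule
    wins and the default is ``noun`` (the most common open class in health
    text).  Intentionally coarse: downstream only needs the 5-tag set.
    """

    def tag(self, surface: str, normalized: str) -> str:
        if not any(c.isalpha() for c in surface):
            return COARSE_FALLBACK
        if normalized in _FUNCTION_WORDS:
            return COARSE_FALLBACK
        for suffix, tag in _SUFFIX_RULES:
            if normalized.endswith(suffix) and len(normalized) > len(suffix) + 1:
                return tag
        return "noun"


def tokenize(
    text: str,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[list[Token]]:
    """Split a document into sentences of tokens.

    Returns a list of sentences; each sentence is a list of :class:`Token`
    in document order.  Empty text yields ``[]``.
    """
    sentences: list[list[Token]] = []
    current: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        tok = Token(
            surface=m.group(),
            normalized=normalize_term(m.group()),
            sentence_index=len(sentences),
            token_index=len(current),
            char_span=(m.start(), m.end()),
        )
        current.append(tok)
        if tok.surface in {".", "!", "?"}:
            if tok.surface == ".":
                prev_word = next((t for t in reversed(current[:-1]) if t.is_word), None)
                if prev_word is not None and prev_word.normalized in abbreviations:
                    continue
            if _BOUNDARY_FOLLOW_RE.match(text, m.end()):
                sentences.append(current)
                current = []
    if current:
        sentences.append(current)
    return sentences


def tag_pos(tokens: list[Token], tagger: Tagger) -> list[Token]:
    """Fill ``pos`` on every token of one sentence, in place.

    A tagger exception downgrades the whole sentence to ``other`` with a
    logged warning rather than failing the document.
    """
    try:
        tags = [tagger.tag(t.surface, t.normalized) for t in tokens]
    except Exception as exc:  # noqa: BLE001 - contract: degrade, never fail
        log.warning("tagger failed on sentence (%s); tagging all tokens 'other'", exc)
        tags = [COARSE_FALLBACK] * len(tokens)
    for tok, tag in zip(tokens, tags):
        tok.pos = tag if tag in {"noun", "verb", "adj", "adv", "other"} else COARSE_FALLBACK
    return tokens


def identify_difficult_terms(
    text: str,
    table: FrequencyTable,
    tagger: Tagger | None = None,
    exemptions: ExemptionPolicy | None = DEFAULT_EXEMPTIONS,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[DifficultTerm]:
    """Flag every non-exempt word token strictly below the threshold.

    Results are in document order, one entry per token occurrence, each
    carrying its corpus frequency and coarse POS.
    """
    tagger = tagger or HeuristicTagger()
    out: list[DifficultTerm] = []
    for sentence in tokenize(text, abbreviations=abbreviations):
        tag_pos(sentence, tagger)
        for tok in sentence:
            if not tok.is_word:
                continue
            if table.is_difficult(tok.surface, exemptions):
                out.append(DifficultTerm(token=tok, frequency=table.familiarity(tok.surface)))
    return out
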
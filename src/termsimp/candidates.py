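"""Easier-alternative generation: collect, filter, and rank substitutes.

This is the second algorithm step.  For a flagged term, all configured
lexical resources are queried; entries become candidates, which survive only
if they would actually ease the text: a single-word synonym or hypernym must
share the term's part of speech and be strictly more familiar (a higher
corpus count) than the term it replaces.  Definitions and semantic types are
not drop-in replacements — the writer inserts them in parentheses or as a
separate sentence — so they are exempt from the POS and frequency tests.

Ranking groups candidates by (source, kind) in a configurable priority
order, then by familiarity descending, so the writer scans synonyms first
and the most familiar option in each group on top.  The tool aims to offer
at least :data:`MIN_ALTERNATIVES` options per term; when fewer exist the set
is marked as falling short rather than padded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from termsimp.identify import DifficultTerm
from termsimp.lexicon import FrequencyTable, LexicalResource, normalize_term

log = logging.getLogger(__name__)

MIN_ALTERNATIVES = 7

#: (source, kind) priority: drop-in replacements first, then lay-dictionary
#: definitions, then terminology definitions and semantic types.
DEFAULT_SOURCE_PRIORITY: tuple[tuple[str, str], ...] = (
    ("wordnet", "synonym"),
    ("wordnet", "hypernym"),
    ("wiktionary_simple", "definition"),
    ("wiktionary_en", "definition"),
    ("umls", "definition"),
    ("umls", "semantic_type"),
)

_WORD_RE = re.compile(r"[^\W_]+(?:['’\-][^\W_]+)*", re.UNICODE)

# function words ignored when scoring the familiarity of a phrase
_PHRASE_STOPWORDS = frozenset(
    """a an the and or of in on at to for from by with as is are was were be that this
    it its which who when""".split()
)


@dataclass(frozen=True)
class Candidate:
    """A proposed substitute for a difficult term.

    ``pos`` is a coarse tag for single-word candidates and ``None`` for
    phrases.  ``familiarity`` is the corpus count for single words and the
    minimum content-word count for phrases (used only for ordering).
    """

    text: str
    kind: str
    source: str
    pos: str | None
    familiarity: int


@dataclass
class CandidateSet:
    """Ranked alternatives for one difficult term."""

    target: DifficultTerm
    candidates: list[Candidate] = field(default_factory=list)

    @property
    def meets_minimum(self) -> bool:
        return len(self.candidates) >= MIN_ALTERNATIVES


def _is_single_word(text: str) -> bool:
    return len(_WORD_RE.findall(text)) == 1 and not any(c.isspace() for c in text.strip())


def phrase_familiarity(text: str, table: FrequencyTable) -> int:
    """Familiarity of a multiword candidate: minimum count over content words.

    A phrase reads as easily as its hardest word; function words are
    ignored.  A phrase with no content words scores 0.
    """
    counts = [
        table.familiarity(w)
        for w in _WORD_RE.findall(text)
        if normalize_term(w) not in _PHRASE_STOPWORDS
    ]
    return min(counts) if counts else 0


def make_candidate(text: str, kind: str, source: str, pos: str | None, table: FrequencyTable) -> Candidate:
    """Build a candidate, computing familiarity per the single-word/phrase rule."""
    if _is_single_word(text):
        return Candidate(text=text, kind=kind, source=source, pos=pos, familiarity=table.familiarity(text))
    return Candidate(text=text, kind=kind, source=source, pos=None, familiarity=phrase_familiarity(text, table))


def filter_candidate(candidate: Candidate, term: DifficultTerm, table: FrequencyTable) -> bool:
    """Decide whether a candidate is a genuine easier alternative.

    Rejects self-replacements always.  Single-word synonyms/hypernyms must
    match the term's POS and be strictly more familiar.  Definitions and
    semantic types pass both tests untested (they are glosses, not
    substitutes).
    """
    if normalize_term(candidate.text) == term.token.normalized:
        return False
    if candidate.kind in {"synonym", "hypernym"} and _is_single_word(candidate.text):
        if candidate.pos != term.token.pos:
            return False
        if candidate.familiarity <= term.frequency:
            return False
    return True


def rank_candidates(
    candidates: Sequence[Candidate],
    source_priority: Sequence[tuple[str, str]] = DEFAULT_SOURCE_PRIORITY,
) -> list[Candidate]:
    """Stable sort by (source, kind) priority, then familiarity descending, then text.

    A (source, kind) pair missing from the priority list sorts last, with a
    warning — the writer still sees the entry, just at the bottom.
    """
    index = {pair: i for i, pair in enumerate(source_priority)}
    unknown_rank = len(source_priority)

    def key(c: Candidate) -> tuple[int, int, str]:
        pos = index.get((c.source, c.kind))
        if pos is None:
            log.warning("unknown (source, kind) %r; ranking it last", (c.source, c.kind))
            pos = unknown_rank
        return (pos, -c.familiarity, c.text)

    return sorted(candidates, key=key)


def generate_candidates(
    term: DifficultTerm,
    resources: Iterable[LexicalResource],
    table: FrequencyTable,
    source_priority: Sequence[tuple[str, str]] = DEFAULT_SOURCE_PRIORITY,
) -> CandidateSet:
    """Full step-2 pipeline for one term: lookup, filter, rank, deduplicate.

    A resource whose lookup raises is skipped with a warning; the remaining
    sources still contribute.  Duplicate texts (case-folded) keep only the
    highest-ranked occurrence.
    """
    raw: list[Candidate] = []
    for resource in resources:
        try:
            entries = resource.lookup(term.token.normalized, term.token.pos)
        except Exception as exc:  # noqa: BLE001 - contract: degrade per source
            log.warning("resource %r failed for %r: %s", getattr(resource, "source", "?"), term.token.surface, exc)
            continue
        for entry in entries:
            raw.append(make_candidate(entry.text, entry.kind, entry.source, entry.pos, table))
    kept = [c for c in raw if filter_candidate(c, term, table)]
    ranked = rank_candidates(kept, source_priority)
    seen: set[str] = set()
    unique: list[Candidate] = []
    for c in ranked:
        key = normalize_term(c.text)
        if key in seen:
            continue
        seen.add(key)
        unique.append(c)
    return CandidateSet(target=term, candidates=unique)
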
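"""Background frequency model (term familiarity) and lexical-resource contract.

Term familiarity is the number of times a word occurs in a very large
general-language corpus of web text.  A word a reader rarely encounters is
assumed unfamiliar and therefore difficult.  The familiarity model here is a
plain unigram table (``term -> count``) with a difficulty threshold: any
non-exempt word whose count falls strictly below the threshold is flagged.
The default threshold, 15,377,914 occurrences, is the count of the 5000th
most frequent web unigram, i.e. difficulty begins outside a reader's core
5000-word vocabulary.

Candidate substitutes come from pluggable lexical resources (a thesaurus
providing synonyms and hypernyms, a medical terminology providing
definitions and semantic types, lay dictionaries providing definitions).
The :class:`LexicalResource` protocol abstracts over their access so tests
and deployments can back them with plain TSV files.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

log = logging.getLogger(__name__)

#: Corpus count of the 5000th most frequent web unigram; terms strictly
#: below it are considered difficult.
DEFAULT_THRESHOLD_COUNT = 15_377_914

COARSE_TAGS = frozenset({"noun", "verb", "adj", "adv", "other"})
CANDIDATE_KINDS = frozenset({"synonym", "hypernym", "definition", "semantic_type"})
RESOURCE_SOURCES = frozenset({"wordnet", "umls", "wiktionary_en", "wiktionary_simple"})

# kinds each source is allowed to emit
_SOURCE_KINDS = {
    "wordnet": {"synonym", "hypernym"},
    "umls": {"definition", "semantic_type"},
    "wiktionary_en": {"definition"},
    "wiktionary_simple": {"definition"},
}

_EDGE_PUNCT = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)
_NUMERIC = re.compile(r"[\d.,:/\\%-]*\d[\d.,:/\\%-]*")


class FrequencyTableError(ValueError):
    """Raised when a frequency file cannot be parsed."""


def normalize_term(term: str) -> str:
    """Normalize a surface form for frequency lookup.

    Unicode NFC, case-fold, strip leading/trailing punctuation; internal
    hyphens and apostrophes are kept.  Applied identically at table load and
    at lookup so the two sides can never disagree.
    """
    term = unicodedata.normalize("NFC", term).casefold()
    return _EDGE_PUNCT.sub("", term)


@dataclass(frozen=True)
class ExemptionPolicy:
    """Token classes never flagged as difficult.

    Pure numbers, pure punctuation, and single characters have no meaningful
    dictionary alternative, so flagging them would only add noise to the
    writer's worksheet.  Each class can be switched off.
    """

    exempt_numbers: bool = True
    exempt_punctuation: bool = True
    exempt_single_chars: bool = True

    def is_exempt(self, term: str) -> bool:
        norm = normalize_term(term)
        if self.exempt_punctuation and not any(c.isalnum() for c in term):
            return True
        if norm == "":
            # nothing left after stripping punctuation
            return self.exempt_punctuation
        if self.exempt_numbers and _NUMERIC.fullmatch(norm):
            return True
        if self.exempt_single_chars and len(norm) <= 1:
            return True
        return False


DEFAULT_EXEMPTIONS = ExemptionPolicy()


@dataclass
class FrequencyTable:
    """Unigram corpus counts plus the familiarity threshold.

    ``entries`` maps normalized terms to non-negative occurrence counts.
    Lookups of absent terms yield 0 — an unseen word is maximally
    unfamiliar.
    """

    entries: dict[str, int] = field(default_factory=dict)
    threshold_count: int = DEFAULT_THRESHOLD_COUNT
    name: str = ""

    def __post_init__(self) -> None:
        if self.threshold_count < 0:
            raise ValueError("threshold_count must be >= 0")
        for term, count in self.entries.items():
            if count < 0:
                raise ValueError(f"negative count for {term!r}")

    def familiarity(self, term: str) -> int:
        """Corpus count for ``term`` (0 if absent).  Total on non-empty strings."""
        if not term:
            raise ValueError("term must be non-empty")
        return self.entries.get(normalize_term(term), 0)

    def is_difficult(self, term: str, exemptions: ExemptionPolicy | None = DEFAULT_EXEMPTIONS) -> bool:
        """True iff ``term`` is non-exempt and strictly below the threshold.

        The threshold is strict: a term whose count equals the threshold is
        familiar ("lower frequency" means difficult, equality does not).
        """
        if exemptions is not None and exemptions.is_exempt(term):
            return False
        return self.familiarity(term) < self.threshold_count


def load_frequency_table(
    path: str | Path,
    threshold_count: int = DEFAULT_THRESHOLD_COUNT,
    name: str | None = None,
) -> FrequencyTable:
    """Load a 2-column TSV ``term<TAB>count`` file (no header, UTF-8).

    Rows are normalized on load; duplicate normalized terms have their
    counts summed.  Malformed rows (wrong column count, non-integer or
    negative count) raise :class:`FrequencyTableError` naming the line.
    """
    if threshold_count < 0:
        raise FrequencyTableError("threshold_count must be >= 0")
    path = Path(path)
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FrequencyTableError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            term, raw_count = parts
            try:
                count = int(raw_count)
            except ValueError:
                raise FrequencyTableError(
                    f"{path}:{lineno}: count {raw_count!r} is not an integer"
                ) from None
            if count < 0:
                raise FrequencyTableError(f"{path}:{lineno}: negative count {count}")
            norm = normalize_term(term)
            entries[norm] = entries.get(norm, 0) + count
    return FrequencyTable(entries=entries, threshold_count=threshold_count, name=name or path.name)


@dataclass(frozen=True)
class ResourceEntry:
    """One substitute suggestion as stored in a lexical resource.

    ``text`` may be a word, a phrase, or a full definition sentence.  Kind
    and source are constrained to the combinations the backing resources can
    actually produce (synonyms/hypernyms only from the thesaurus, semantic
    types only from the medical terminology).
    """

    headword: str
    pos: str
    kind: str
    source: str
    text: str

    def __post_init__(self) -> None:
        if self.kind not in CANDIDATE_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.source not in RESOURCE_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.kind not in _SOURCE_KINDS[self.source]:
            raise ValueError(f"source {self.source!r} cannot supply kind {self.kind!r}")
        if self.pos not in COARSE_TAGS:
            raise ValueError(f"unknown pos {self.pos!r}")
        if not self.text:
            raise ValueError("entry text must be non-empty")


@runtime_checkable
class LexicalResource(Protocol):
    """Contract for anything that can supply substitute entries."""

    source: str

    def lookup(self, headword: str, pos: str) -> list[ResourceEntry]:
        """Entries for the normalized headword; deterministic for fixed data."""
        ...


class TsvLexicalResource:
    """Lexical resource backed by a TSV file.

    File dialect: ``headword<TAB>pos<TAB>kind<TAB>source<TAB>text``, no
    header, UTF-8.  Stands in for thesaurus / terminology / dictionary
    dumps, whose licensing prevents shipping them.
    """

    def __init__(self, path: str | Path, source: str | None = None):
        path = Path(path)
        self._by_headword: dict[str, list[ResourceEntry]] = {}
        sources: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line == "":
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(
                        f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                    )
                headword, pos, kind, src, text = parts
                entry = ResourceEntry(
                    headword=normalize_term(headword), pos=pos, kind=kind, source=src, text=text
                )
                self._by_headword.setdefault(entry.headword, []).append(entry)
                sources.add(src)
        if source is not None:
            self.source = source
        elif len(sources) == 1:
            self.source = next(iter(sources))
        else:
            self.source = "mixed"

    def lookup(self, headword: str, pos: str) -> list[ResourceEntry]:
        # pos is not used to pre-filter: the candidate filter decides which
        # entries survive, and definitions are exempt from the POS test.
        return list(self._by_headword.get(normalize_term(headword), ()))


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
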
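"""Document statistics: word/sentence/syllable counts and Flesch-Kincaid grade.

The Flesch-Kincaid Grade Level maps average sentence length and average
syllables per word to a US school grade:

    FK = 0.39 * (words / sentences) + 11.8 * (syllables / words) - 15.59

Different tools disagree on FK for the same text because they count
syllables and sentences differently, so this module freezes one dialect:
sentences come from the same rule-based splitter the identification step
uses; a word is any token containing a letter or digit (hyphenated forms are
one word); syllables are counted by a dictionary-free heuristic — maximal
vowel runs (a e i o u y), minus a silent terminal "e" (kept when a consonant
precedes a final "-le", as in "table"), minimum one per word.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from termsimp.identify import DEFAULT_ABBREVIATIONS, tokenize

_VOWEL_RUN = re.compile(r"[aeiouy]+")
_LETTERS = re.compile(r"[^a-z]")


@dataclass
class TextStats:
    """Counts and readability grade for one document.

    ``fk_grade`` is ``None`` (missing, not zero) for empty text.
    """

    word_count: int
    sentence_count: int
    syllable_count: int
    fk_grade: float | None
    label: str = ""


def count_syllables(word: str) -> int:
    """Heuristic syllable count for one word; numeric tokens count as one."""
    w = _LETTERS.sub("", word.casefold())
    if not w:
        return 1
    n = len(_VOWEL_RUN.findall(w))
    if w.endswith("e") and n > 1:
        # terminal e is silent unless it carries a consonant+le syllable
        if not (w.endswith("le") and len(w) >= 3 and w[-3] not in "aeiouy"):
            n -= 1
    return max(n, 1)


def fk_grade_level(words: int, sentences: int, syllables: int) -> float | None:
    if words == 0 or sentences == 0:
        return None
    return 0.39 * (words / sentences) + 11.8 * (syllables / words) - 15.59


def text_stats(text: str, label: str = "", abbreviations=DEFAULT_ABBREVIATIONS) -> TextStats:
    """Word, sentence, and syllable counts plus FK grade for a document."""
    sentences = tokenize(text, abbreviations=abbreviations)
    words = [tok for sent in sentences for tok in sent if tok.is_word]
    syllables = sum(count_syllables(tok.surface) for tok in words)
    return TextStats(
        word_count=len(words),
        sentence_count=len(sentences),
        syllable_count=syllables,
        fk_grade=fk_grade_level(len(words), len(sentences), syllables),
        label=label,
    )


@dataclass
class PairedStats:
    """Per-text statistics for aligned original/simplified pairs, with means."""

    original: list[TextStats]
    simplified: list[TextStats]

    def means(self, side: str) -> dict[str, float | None]:
        stats: Sequence[TextStats] = getattr(self, side)
        n = len(stats)
        fk = [s.fk_grade for s in stats if s.fk_grade is not None]
        return {
            "word_count": sum(s.word_count for s in stats) / n,
            "sentence_count": sum(s.sentence_count for s in stats) / n,
            "syllable_count": sum(s.syllable_count for s in stats) / n,
            "fk_grade": sum(fk) / len(fk) if fk else None,
        }


def compare_stats(originals: Sequence[str], simplifications: Sequence[str]) -> PairedStats:
    """Statistics for pairwise-aligned original and simplified texts."""
    if len(originals) != len(simplifications):
        raise ValueError(
            f"length mismatch: {len(originals)} originals vs {len(simplifications)} simplifications"
        )
    if not originals:
        raise ValueError("need at least one pair")
    return PairedStats(
        original=[text_stats(t, label=f"original_{i}") for i, t in enumerate(originals)],
        simplified=[text_stats(t, label=f"simplified_{i}") for i, t in enumerate(simplifications)],
    )
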
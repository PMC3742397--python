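"""Writer worksheet emission and rewrite re-verification.

The tool never rewrites text itself: it emits a worksheet pairing each
original sentence with the same sentence with numbered blanks where the
difficult words were, plus the ranked alternatives for every blank.  A human
writer fills the blanks (grammatical agreement included — the tool never
inflects) and the finished text is re-run through the identification step to
make sure the rewrite introduced no new difficult vocabulary.

Worksheet file dialect: UTF-8 TSV in long form, one line per
(blank, candidate), fixed header, with tab/newline/backslash escaped inside
fields so a write/read/write cycle is byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from termsimp.candidates import (
    DEFAULT_SOURCE_PRIORITY,
    Candidate,
    generate_candidates,
)
from termsimp.identify import (
    DEFAULT_ABBREVIATIONS,
    DifficultTerm,
    HeuristicTagger,
    Tagger,
    tag_pos,
    tokenize,
)
from termsimp.lexicon import (
    DEFAULT_EXEMPTIONS,
    ExemptionPolicy,
    FrequencyTable,
    LexicalResource,
    normalize_term,
)

log = logging.getLogger(__name__)

_HEADER = (
    "sentence_id\tblank_id\toriginal_sentence\tblanked_sentence\tdifficult_surface"
    "\trank\tcandidate_text\tkind\tsource\tpos\tfamiliarity"
)

_PLACEHOLDER_RE = re.compile(r"____\[(\d+)\]")


class WorksheetParseError(ValueError):
    """Raised when a worksheet file cannot be parsed."""


@dataclass
class WorksheetRow:
    """One difficult surface form in one sentence, with its alternatives.

    Blanks are numbered left to right per sentence by first occurrence of
    each distinct surface form; a surface repeated within the sentence
    reuses its number, so replacing every ``____[k]`` placeholder with that
    row's surface reconstructs the original sentence byte-exactly.
    """

    sentence_id: int
    original_sentence: str
    blanked_sentence: str
    blank_id: int
    difficult_surface: str
    alternatives: list[Candidate] = field(default_factory=list)


@dataclass
class VerificationReport:
    """Outcome of re-running identification on a rewritten text."""

    remaining: list[DifficultTerm]
    introduced: list[DifficultTerm]

    @property
    def counts(self) -> dict[str, int]:
        return {"remaining": len(self.remaining), "introduced": len(self.introduced)}


def reconstruct_sentence(rows: Sequence[WorksheetRow]) -> str:
    """Fill every placeholder in a sentence's blanked form with its surface."""
    if not rows:
        raise ValueError("need at least one row")
    text = rows[0].blanked_sentence
    surfaces = {row.blank_id: row.difficult_surface for row in rows}

    def fill(m: re.Match[str]) -> str:
        return surfaces[int(m.group(1))]

    return _PLACEHOLDER_RE.sub(fill, text)


def build_worksheet(
    text: str,
    table: FrequencyTable,
    tagger: Tagger | None = None,
    resources: Iterable[LexicalResource] = (),
    exemptions: ExemptionPolicy | None = DEFAULT_EXEMPTIONS,
    source_priority=DEFAULT_SOURCE_PRIORITY,
    abbreviations=DEFAULT_ABBREVIATIONS,
) -> list[WorksheetRow]:
    """One row per (sentence, distinct difficult surface form), document order.

    Repeated difficult words in one sentence share one row (and one
    candidate set).  Sentences with no difficult words produce no rows.
    """
    tagger = tagger or HeuristicTagger()
    resources = list(resources)
    rows: list[WorksheetRow] = []
    for sent_id, sentence in enumerate(tokenize(text, abbreviations=abbreviations)):
        tag_pos(sentence, tagger)
        difficult = [
            tok
            for tok in sentence
            if tok.is_word and table.is_difficult(tok.surface, exemptions)
        ]
        if not difficult:
            continue
        sent_start = sentence[0].char_span[0]
        sent_end = sentence[-1].char_span[1]
        original = text[sent_start:sent_end]

        # number distinct surfaces by first occurrence
        blank_ids: dict[str, int] = {}
        first_token: dict[str, object] = {}
        for tok in difficult:
            if tok.surface not in blank_ids:
                blank_ids[tok.surface] = len(blank_ids) + 1
                first_token[tok.surface] = tok

        blanked = original
        for tok in reversed(difficult):  # right-to-left keeps spans valid
            start = tok.char_span[0] - sent_start
            end = tok.char_span[1] - sent_start
            blanked = blanked[:start] + f"____[{blank_ids[tok.surface]}]" + blanked[end:]

        for surface, k in blank_ids.items():
            tok = first_token[surface]
            term = DifficultTerm(token=tok, frequency=table.familiarity(surface))
            cand_set = generate_candidates(term, resources, table, source_priority)
            if not cand_set.meets_minimum:
                log.warning(
                    "only %d alternative(s) for %r (goal: 7)", len(cand_set.candidates), surface
                )
            rows.append(
                WorksheetRow(
                    sentence_id=sent_id,
                    original_sentence=original,
                    blanked_sentence=blanked,
                    blank_id=k,
                    difficult_surface=surface,
                    alternatives=cand_set.candidates,
                )
            )
    return rows


def _escape(value: str) -> str:
    return (
        value.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n").replace("\r", "\\r")
    )


def _unescape(value: str) -> str:
    out: list[str] = []
    it = iter(range(len(value)))
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            nxt = value[i + 1]
            mapped = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt)
            if mapped is not None:
                out.append(mapped)
                i += 2
                continue
        out.append(c)
        i += 1
    return "".join(out)


def write_worksheet(rows: Sequence[WorksheetRow], path: str | Path) -> None:
    """Write rows as long-form TSV; a blank with no alternatives still gets a line."""
    lines = [_HEADER]
    for row in rows:
        base = [
            str(row.sentence_id),
            str(row.blank_id),
            _escape(row.original_sentence),
            _escape(row.blanked_sentence),
            _escape(row.difficult_surface),
        ]
        if not row.alternatives:
            lines.append("\t".join(base + ["", "", "", "", "", ""]))
            continue
        for rank, cand in enumerate(row.alternatives, start=1):
            lines.append(
                "\t".join(
                    base
                    + [
                        str(rank),
                        _escape(cand.text),
                        cand.kind,
                        cand.source,
                        cand.pos or "",
                        str(cand.familiarity),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_worksheet(path: str | Path) -> list[WorksheetRow]:
    """Inverse of :func:`write_worksheet`; raises with the offending line number."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").split("\n")
    if not lines or lines[0] != _HEADER:
        raise WorksheetParseError(f"{path}:1: bad or missing header")
    rows: dict[tuple[int, int], WorksheetRow] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split("\t")
        if len(parts) != 11:
            raise WorksheetParseError(f"{path}:{lineno}: expected 11 columns, got {len(parts)}")
        try:
            sentence_id = int(parts[0])
            blank_id = int(parts[1])
        except ValueError:
            raise WorksheetParseError(f"{path}:{lineno}: non-integer id") from None
        key = (sentence_id, blank_id)
        if key not in rows:
            rows[key] = WorksheetRow(
                sentence_id=sentence_id,
                blank_id=blank_id,
                original_sentence=_unescape(parts[2]),
                blanked_sentence=_unescape(parts[3]),
                difficult_surface=_unescape(parts[4]),
            )
        if parts[5] == "":
            continue  # row without alternatives
        try:
            familiarity = int(parts[10])
        except ValueError:
            raise WorksheetParseError(f"{path}:{lineno}: non-integer familiarity") from None
        rows[key].alternatives.append(
            Candidate(
                text=_unescape(parts[6]),
                kind=parts[7],
                source=parts[8],
                pos=parts[9] or None,
                familiarity=familiarity,
            )
        )
    return list(rows.values())


def verify_rewrite(
    original_text: str,
    rewritten_text: str,
    table: FrequencyTable,
    tagger: Tagger | None = None,
    exemptions: ExemptionPolicy | None = DEFAULT_EXEMPTIONS,
) -> VerificationReport:
    """Re-run identification on a rewrite and split out newly introduced terms.

    ``remaining`` is every difficult term still present in the rewritten
    text; ``introduced`` is the subset whose normalized surface never occurs
    in the original — vocabulary the writer added that itself needs
    simplifying.
    """
    from termsimp.identify import identify_difficult_terms  # local to avoid cycle

    if not original_text or not rewritten_text:
        raise ValueError("both texts must be non-empty")
    remaining = identify_difficult_terms(rewritten_text, table, tagger, exemptions)
    original_words = {
        tok.normalized for sent in tokenize(original_text) for tok in sent if tok.is_word
    }
    introduced = [t for t in remaining if t.token.normalized not in original_words]
    return VerificationReport(remaining=remaining, introduced=introduced)
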
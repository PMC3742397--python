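"""Shared fixtures: tiny frequency tables, resource files, and taggers."""

from __future__ import annotations

import pytest

from termsimp.identify import DictionaryTagger
from termsimp.lexicon import FrequencyTable, TsvLexicalResource


@pytest.fixture
def small_table() -> FrequencyTable:
    """A handful of terms around a web-scale threshold."""
    return FrequencyTable(
        entries={
            "disease": 80_000_000,
            "cirrhosis": 120_000,
            "disorder": 2_000_000,
            "symptom": 30_000_000,
            "breathlessness": 2_000_000,
            "dyspnea": 1_000,
        },
        threshold_count=15_377_914,
        name="small",
    )


@pytest.fixture
def freq_file(tmp_path):
    """Factory writing a term->count TSV and returning its path."""

    def make(rows: dict[str, int] | list[tuple[str, int]], name: str = "freq.tsv"):
        items = rows.items() if isinstance(rows, dict) else rows
        path = tmp_path / name
        path.write_text("".join(f"{t}\t{c}\n" for t, c in items), encoding="utf-8")
        return path

    return make


@pytest.fixture
def resource_file(tmp_path):
    """Factory writing a 5-column resource TSV and returning a TsvLexicalResource."""

    def make(rows: list[tuple[str, str, str, str, str]], name: str = "res.tsv"):
        path = tmp_path / name
        path.write_text("".join("\t".join(r) + "\n" for r in rows), encoding="utf-8")
        return TsvLexicalResource(path)

    return make


@pytest.fixture
def fixture_tagger() -> DictionaryTagger:
    return DictionaryTagger(
        {
            "disorder": "noun",
            "disease": "noun",
            "dyspnea": "noun",
            "symptom": "noun",
            "breathlessness": "noun",
            "cirrhosis": "noun",
            "crystallizes": "verb",
            "gout": "noun",
        }
    )
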
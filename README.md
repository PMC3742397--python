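# termsimp

Lexical simplification of consumer health text driven by **term familiarity**,
with the evaluation machinery to measure whether simplification actually
helps readers.

Health education text is routinely too hard for the people it is written
for. `termsimp` supports a human writer in fixing that, one word at a time:

1. **Identify** — every word is looked up in a unigram frequency table from
   a very large general-language web corpus. A word whose count falls
   strictly below a threshold (by default 15,377,914 — the count of the
   5000th most frequent web unigram) is unfamiliar to lay readers and is
   flagged for replacement. Pure numbers, punctuation, and single
   characters are exempt.
2. **Suggest** — for each flagged term, easier alternatives are collected
   from pluggable lexical resources: synonyms and hypernyms from a
   thesaurus, definitions and semantic types from a medical terminology,
   definitions from lay dictionaries. A single-word synonym or hypernym is
   kept only if it has the *same part of speech* and a *strictly higher*
   corpus frequency than the word it replaces; definitions and semantic
   types are glosses (inserted in parentheses or as an extra sentence), so
   they bypass those filters. Candidates are ranked by source, then by
   familiarity descending, aiming to offer at least 7 options per term.
3. **Worksheet** — the writer receives a TSV pairing each original sentence
   with the same sentence with numbered blanks (`____[1]`, `____[2]`, …)
   and the ranked alternatives for each blank. The writer chooses; the tool
   never rewrites or inflects.
4. **Verify** — the rewritten text is re-run through step 1 to confirm that
   nothing the writer added is itself difficult.

A companion evaluation layer (`termsimp-study`) scores reader-study
response tables on four metric families — perceived difficulty (5-point
Likert, 1 = Very Easy), understanding (% correct with the text visible),
learning (percentage-point pre/post gain), and retention (free-recall fact
counts with two-grader ±1 scoring and third-grader reconciliation) — with a
paired *t*-test, a 2×2 simplification-by-topic ANOVA, and Pearson
correlations against covariates. A synthetic-study generator
(`termsimp-synth`) produces cohorts with known ground truth so every
estimator is testable without any licensed corpus or private study data.

## Worked example

The published study snippet about gout, original vs writer-simplified:

```bash
termsimp stats --text gout_original.txt --pair gout_simplified.txt
```

```
metric	original	simplified
Word count	32	37
Sentence count	1	1
Syllable count	60	62
Flesch-Kincaid grade level	19.0	18.6
```

Lexical simplification *added* five words (glosses such as "(uric acid)"
stay in the text) yet still lowered the Flesch-Kincaid grade — replacing
rare polysyllables like "precipitating" with "collect" buys more than the
extra words cost. This is the expected signature of familiarity-driven
simplification: length up, difficulty down.

On the library side the same pipeline is three calls:

```python
from termsimp import load_frequency_table, identify_difficult_terms, build_worksheet

table = load_frequency_table("frequency.tsv", threshold_count=15_377_914)
flagged = identify_difficult_terms(text, table)        # step 1
rows = build_worksheet(text, table, resources=[...])   # steps 2-3
```

## Command-line tools

| command | purpose |
|---|---|
| `termsimp identify` | flag difficult terms in a text |
| `termsimp suggest` | ranked alternatives for one term |
| `termsimp worksheet` | emit the writer worksheet TSV |
| `termsimp verify` | re-check a rewritten text |
| `termsimp stats` | word/sentence counts and FK grade |
| `termsimp-study score` | score a study response CSV (all metrics + statistics) |
| `termsimp-synth lexicon` / `study` | generate synthetic fixtures / cohorts |

File dialects (frequency TSV, resource TSV, worksheet TSV, response CSV)
are documented in the module docstrings and `docs/response-schema.md`;
the scientific background and design choices are in `docs/methods.md`.
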
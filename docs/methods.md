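# Methods

## The model: difficulty as (un)familiarity

`termsimp` operationalizes word difficulty as corpus frequency: a reader
who rarely meets a word will find it hard. The background model is a
unigram table of occurrence counts from a very large general-language web
corpus, and the difficulty rule is a strict threshold — a word is flagged
iff its count is *strictly below* `threshold_count`. The default,
15,377,914, is the count of the 5000th most frequent web unigram, i.e. the
edge of a core 5000-word vocabulary. Equality at the threshold is familiar;
absent words count 0 and are therefore always flagged (an unseen word is
maximally unfamiliar). Only unigrams are modeled; multiword medical phrases
("purine metabolism") are flagged word-by-word, not as units.

Assumptions worth stating: frequency in a *general* web corpus is the right
proxy for lay readers (a medical corpus would inflate the familiarity of
jargon); surface forms are looked up as written (no lemmatization — an
inflected form must earn its own frequency); and difficulty is a property
of the word, not the sentence.

### Normalization and exemptions

Terms are NFC-normalized, case-folded, and stripped of leading/trailing
punctuation; internal hyphens are kept. The same function runs at table
load and lookup, so the two can never disagree. Pure numbers, pure
punctuation, and single characters are exempt from flagging by default
(configurable): they have no dictionary alternative a writer could use.

## Candidate generation and ranking

Alternatives come from pluggable resources declaring one of four kinds:
`synonym`, `hypernym` (thesaurus), `definition` (lay dictionaries,
terminology), `semantic_type` (terminology). Filters:

* self-replacements are always rejected (case-insensitive);
* a **single-word synonym or hypernym** must match the flagged term's
  coarse POS (noun/verb/adj/adv/other) and have a **strictly higher**
  corpus count — it must be a drop-in replacement that is actually easier.
  The frequency test is read as applying to hypernyms as well as synonyms:
  both are offered as direct substitutes, so both must be more familiar;
* definitions and semantic types bypass the POS and frequency tests: the
  writer inserts them as parenthetical glosses or separate sentences, not
  as substitutes.

Ranking is a stable sort on ((source, kind) priority, familiarity
descending, text). The default priority — thesaurus synonym > hypernym >
simple-dictionary definition > full-dictionary definition > terminology
definition > semantic type — puts drop-in replacements first; it is a
package choice (the original workflow sorted by source without stating an
order) and is configurable. A multiword candidate's familiarity, used only
for ordering, is the minimum count over its content words: a phrase reads
as easily as its hardest word. Duplicate texts keep the highest-priority
occurrence. Seven alternatives per term is a reporting goal, not a
guarantee: with fewer, the set is marked short and the CLI warns, but
nothing is padded.

Word-sense disambiguation is deliberately absent: all senses' alternatives
are shown and the human writer chooses.

## Tokenization, tagging, syllables — frozen dialects

No pretrained NLP stack is required; the three text primitives are small,
deterministic rules, frozen so counts are reproducible:

* **Tokens**: maximal runs of letters/digits with internal hyphens or
  apostrophes, plus single punctuation characters; every token carries
  half-open character offsets into the source document, so blanking and
  reconstruction are byte-exact.
* **Sentences**: split after `.` `!` `?` when followed by whitespace and an
  uppercase letter (optionally an opening quote/bracket), unless the
  preceding word is in a configurable abbreviation list.
* **POS**: a 5-tag coarse set. Taggers are a contract; the package ships a
  dictionary tagger (fixtures, tagged lexicons) and a suffix-heuristic
  tagger (function-word list, suffix rules, default noun). A tagger
  failure degrades the sentence to `other` with a warning rather than
  aborting.
* **Syllables**: maximal runs of `aeiouy`, minus a silent terminal "e"
  (kept when a consonant precedes final "-le", as in "table"), minimum one
  per word. Flesch-Kincaid is then the standard
  `0.39·(words/sentences) + 11.8·(syllables/words) − 15.59`, reported as
  missing (never 0) for empty text. FK tools disagree on the same text
  precisely because these dialects vary, which is why this one is pinned
  by tests; published FK values from other tools should be compared with
  tolerance, while word and sentence counts compare exactly.

On the one published stimulus pair available to this repository (the gout
sentence), the dialect gives 32/37 words and FK 19.0/18.6. The full asthma
and liver-cirrhosis study documents were distributed only as an external
supplement; their table of word/sentence/FK values cannot be recomputed
here, and the corresponding acceptance test states that rather than passing
on substitute text.

## Worksheet and re-verification

One worksheet row per (sentence, distinct difficult surface form); blanks
are numbered left-to-right by first occurrence, and a surface repeated in
one sentence reuses its number, so filling every `____[k]` with that row's
surface reconstructs the sentence byte-exactly (an invariant under test).
Grammatical agreement after substitution is explicitly the writer's job.
Re-verification runs identification on the rewritten text and splits the
flags into `remaining` and `introduced` (normalized surface absent from
the original) — writer-added vocabulary is held to the same threshold.
There is no information-preservation check; that is editorial.

## Study evaluation

Scoring follows the study design it emulates: a balanced within-subject
2×2 (topic × version), five Likert-rated snippet pairs, 5 with-text
questions (understanding = % correct), 7 myth-based questions before and
after (learning = percentage-point gain), free recall graded +1/−1 per
fact by two blinded graders. Choices the design left open:

* **Paired t-test pooling**: per-participant mean Likert difference
  (original − simplified), two-sided. Zero variance of differences is
  flagged as undefined, never a fabricated p.
* **ANOVA**: fixed-effects `score ~ version * topic` via ordinary least
  squares (statsmodels), Type-I sums of squares (equal to all types on
  balanced data); an independent hand sums-of-squares oracle checks it in
  tests. Cells need ≥ 2 observations; an exactly-constant response is
  reported as zero residual variance, not an F.
* **Grader reconciliation**: ">100% divergence" is read conservatively as
  `|a−b| > min(|a|,|b|)` (any disagreement when one grade is 0 escalates).
  Under agreement the reconciled grade is the mean of the two graders;
  under divergence the third grader's score is final, and if it is absent
  the result is an explicit escalation, never a number.
* **Missing forced-choice answers** count as incorrect, with a logged
  warning. Education and language-skill codes are ordinal, higher = more.
* **Grading sheets** are emitted with per-grader shuffled fact order, no
  condition columns, and the shuffle seed recorded.

## Synthetic-study generator

The generator exists so every estimator can be validated against known
truth. Its defaults are the emulated study's aggregates: 105 completers,
6 attention-check failures (99 analyzed); understanding probabilities
0.52/0.63 per question by version, with an 8-point asthma-minus-cirrhosis
spread (the study found asthma easier; the magnitude is a package choice —
the published F values for the two main effects are identical, which looks
typographical, so no magnitude could be taken from them); learning 0.35
pre for everyone, post 0.44/0.53 by version (gains of 9 and 18 points)
with a 14-point cirrhosis-minus-asthma topic spread and no built-in
interaction; Likert means 3.2/2.3, SD 1.0; recall line counts Poisson with
means 4.66/5.04 and a 5% false-fact rate over a closed template
vocabulary (so graded scores have known truth); covariate marginals from
the study's demographic table.

Two parameters are calibrated analytically so estimators are *unbiased*
for the configured targets:

* **Likert location**: round-and-clip of N(μ, σ) onto {1..5} biases the
  mean toward 3, so μ is solved (exact bin probabilities, Brent's method)
  such that the discretized mean equals the target.
* **Education effect**: the target education→understanding Pearson r
  (default 0.25) is induced through a per-SD shift `b` on answer
  probabilities. Binomial question noise attenuates the correlation; with
  pooled understanding U = mean of two topic percentages (5 questions
  each) and standardized education e,
  `r = 100·b / sqrt(500·S + 9000·b²)` where `S` is the average over
  condition patterns of `Σ p(1−p)` across the participant's two cells;
  this is solved for `b` in closed form. A 40,000-participant check
  reproduces the target to the third decimal.

Condition assignment cycles the four (first-topic × first-version)
patterns, so n divisible by 4 is exactly balanced and remainders go
round-robin. Everything is drawn from one seeded generator: identical
seeds give byte-identical output files.

What the generator does **not** emulate: real free-recall prose (closed
templates only), answer-choice confusion structure, participant dropout
before completion, or serial-position effects across the five snippets.
Recovery tests therefore validate the estimators and the statistical
pipeline, not claims about human readers.

## Problem sizes and numerical notes

Recovery tests use 200 replicate cohorts at the study's n (105 → 99) —
enough for Monte-Carlo standard errors around 0.003 Likert points / 0.16
understanding points, against which estimator bias would be visible; the
acceptance script averages 100 replicates. Tolerances: recovery asserts
|replicate mean − target| ≤ 4 MC standard errors plus a small fixed
allowance (0.02 Likert points, 0.2 percentage points, 0.01 on r) for the
deterministic design imbalance at n = 105 and ordinal rounding. The ANOVA
degeneracy check treats residual mean squares below 1e−12 of the response's
mean square as zero (least-squares residue on constant data is otherwise a
0/0 ratio of rounding noise). Ties in ranking break lexicographically,
then by input order (stable sort).

## Known limitations

* Unigram-only difficulty: collocations and phrases are not assessed as
  units, and a common word used in a rare technical sense is never
  flagged.
* Surface-form lookup: morphology-rich rewrites can dodge or attract
  flags through inflection frequency differences.
* The suffix-heuristic tagger is coarse; with it, POS filtering of
  candidates is only as good as its rules. Supplying a dictionary tagger
  or collapsing an external tagger's output to the 5-tag set is preferred
  for production use.
* The syllable heuristic is a dialect, not ground truth; FK values are
  comparable within this package, approximately comparable across tools.
* The evaluation layer assumes the fixed instrument sizes (5/7/5 items,
  5 snippet pairs) of the design it emulates.
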
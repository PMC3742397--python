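"""Scoring and statistics for the reader study of simplified vs original text.

The study design is a balanced within-subject 2x2: every participant reads
one topic (asthma or liver cirrhosis) in its original wording and the other
topic simplified, then rates five original/simplified sentence pairs on a
5-point Likert scale (1 = Very Easy, 5 = Very Hard), and finally free-recalls
facts from both texts.  Four metric families are computed:

* perceived difficulty — mean Likert score per version, paired t-test on
  per-participant mean differences;
* understanding — percent correct on 5 multiple-choice questions answered
  with the text visible;
* learning — percentage-point gain on 7 myth-based questions asked before
  and after reading (participants are their own controls);
* retention — free-recall fact/word/unique-word counts, with facts graded
  +1 (correct) / -1 (incorrect) by two independent graders and a third
  grader breaking large disagreements.

Participants who miss any qualifying (attention-check) question are dropped
before analysis.  The omnibus tests are a two-way fixed-effects ANOVA
(simplification x topic, with interaction) and two-tailed Pearson
correlations against participant covariates (education, language skill,
stress, health literacy).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from termsimp.lexicon import normalize_term

log = logging.getLogger(__name__)

TOPICS = ("asthma", "cirrhosis")
VERSIONS = ("original", "simplified")

N_UNDERSTANDING = 5
N_LEARNING = 7
N_SNIPPETS = 5

_WORD_RE = re.compile(r"[^\W_]+(?:['’\-][^\W_]+)*", re.UNICODE)


def other_topic(topic: str) -> str:
    return TOPICS[1] if topic == TOPICS[0] else TOPICS[0]


def other_version(version: str) -> str:
    return VERSIONS[1] if version == VERSIONS[0] else VERSIONS[0]


@dataclass
class ParticipantRecord:
    """One respondent: condition, answers, recall lines, covariates.

    ``likert[version]`` holds the five snippet ratings for that version;
    ``mc_pre``/``mc_post`` hold 7 correctness flags per topic and
    ``mc_during`` 5 per topic.  ``covariates`` carries ordinal education and
    language-skill codes (higher = more) and the raw stress and
    health-literacy instrument scores.
    """

    participant_id: str
    first_topic: str
    first_version: str
    qualifiers: list[bool]
    likert: dict[str, list[int]]
    mc_pre: dict[str, list[bool]]
    mc_during: dict[str, list[bool]]
    mc_post: dict[str, list[bool]]
    recall: dict[str, list[str]]
    covariates: dict[str, float] = field(default_factory=dict)

    def version_for(self, topic: str) -> str:
        return self.first_version if topic == self.first_topic else other_version(self.first_version)

    def __post_init__(self) -> None:
        if self.first_topic not in TOPICS:
            raise ValueError(f"unknown topic {self.first_topic!r}")
        if self.first_version not in VERSIONS:
            raise ValueError(f"unknown version {self.first_version!r}")
        for version, scores in self.likert.items():
            if any(not 1 <= s <= 5 for s in scores):
                raise ValueError(f"Likert scores out of range for {version}: {scores}")


@dataclass
class StatResult:
    """One inferential result: a t, F, or r statistic with df and p.

    ``statistic``/``p_value`` are ``None`` when the test is degenerate
    (zero variance); ``note`` says why instead of fabricating a number.
    """

    kind: str
    statistic: float | None
    df: tuple[float, ...] | float | None
    p_value: float | None
    direction: str | None = None
    note: str | None = None

    @property
    def defined(self) -> bool:
        return self.statistic is not None and self.p_value is not None


def filter_qualifying(records: Iterable[ParticipantRecord]) -> tuple[list[ParticipantRecord], list[str]]:
    """Keep only participants who answered every qualifying question correctly."""
    kept: list[ParticipantRecord] = []
    dropped: list[str] = []
    for rec in records:
        if not rec.qualifiers:
            raise ValueError(f"participant {rec.participant_id} has no qualifier flags")
        if all(rec.qualifiers):
            kept.append(rec)
        else:
            dropped.append(rec.participant_id)
    return kept, dropped


# ---------------------------------------------------------------------------
# perceived difficulty


@dataclass
class PerceivedDifficulty:
    per_sentence_means: pd.DataFrame  # index: snippet 0..4, columns: versions
    pooled_means: dict[str, float]
    ttest: StatResult


def paired_ttest(differences: Sequence[float]) -> StatResult:
    """Two-sided paired t on per-participant differences; degenerate -> flagged."""
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2 or float(np.std(d, ddof=1)) == 0.0:
        return StatResult(
            kind="t", statistic=None, df=float(max(n - 1, 0)), p_value=None,
            note="zero variance of differences" if n >= 2 else "fewer than 2 pairs",
        )
    t, p = sps.ttest_rel(d, np.zeros_like(d))
    direction = "first larger" if d.mean() > 0 else ("second larger" if d.mean() < 0 else "equal")
    return StatResult(kind="t", statistic=float(t), df=float(n - 1), p_value=float(p), direction=direction)


def perceived_difficulty(records: Sequence[ParticipantRecord]) -> PerceivedDifficulty:
    """Mean Likert per snippet and version, pooled means, and the paired t-test.

    The t-test is on per-participant mean(original) - mean(simplified); a
    positive mean difference means the original reads harder.
    """
    table = {
        v: np.array([rec.likert[v] for rec in records], dtype=float) for v in VERSIONS
    }
    per_sentence = pd.DataFrame(
        {v: table[v].mean(axis=0) for v in VERSIONS},
        index=pd.RangeIndex(N_SNIPPETS, name="snippet"),
    )
    pooled = {v: float(table[v].mean()) for v in VERSIONS}
    diffs = table["original"].mean(axis=1) - table["simplified"].mean(axis=1)
    result = paired_ttest(diffs)
    if result.defined:
        result.direction = "original harder" if diffs.mean() > 0 else "simplified harder"
    return PerceivedDifficulty(per_sentence_means=per_sentence, pooled_means=pooled, ttest=result)


# ---------------------------------------------------------------------------
# understanding / learning / retention


def _count_correct(flags: Sequence[bool | None], expected: int, what: str) -> int:
    if len(flags) != expected:
        raise ValueError(f"expected {expected} {what} flags, got {len(flags)}")
    missing = sum(1 for f in flags if f is None)
    if missing:
        log.warning("%d missing %s answer(s) counted incorrect", missing, what)
    return sum(1 for f in flags if f is True)


def understanding_score(record: ParticipantRecord, topic: str) -> float:
    """Percent correct on the 5 with-text questions for one topic."""
    return 100.0 * _count_correct(record.mc_during[topic], N_UNDERSTANDING, "during-text") / N_UNDERSTANDING


def learning_score(record: ParticipantRecord, topic: str) -> float:
    """Percentage-point gain, post minus pre, on the 7 myth questions."""
    post = _count_correct(record.mc_post[topic], N_LEARNING, "post")
    pre = _count_correct(record.mc_pre[topic], N_LEARNING, "pre")
    return 100.0 * (post - pre) / N_LEARNING


def retention_counts(record: ParticipantRecord, topic: str) -> tuple[int, int, int]:
    """(facts, words, unique words) over the free-recall lines for one topic."""
    lines = [ln for ln in record.recall.get(topic, []) if ln.strip()]
    words = [w for ln in lines for w in _WORD_RE.findall(ln)]
    unique = {normalize_term(w) for w in words}
    return len(lines), len(words), len(unique)


# ---------------------------------------------------------------------------
# free-recall grading


@dataclass(frozen=True)
class ReconciledGrade:
    """Outcome of two-grader reconciliation; never an invented number.

    ``value`` is the mean of the two grades under agreement or the third
    grader's score after escalation; when escalation is needed but no third
    grade was supplied, ``value`` is ``None`` and ``needs_third`` is True.
    """

    value: float | None
    needs_third: bool = False
    used_third: bool = False


def grades_diverge(a: float, b: float) -> bool:
    """More-than-100% divergence, measured against the smaller magnitude.

    With a zero grade on one side, any disagreement counts as divergent.
    """
    if a == b:
        return False
    smaller = min(abs(a), abs(b))
    if smaller == 0:
        return True
    return abs(a - b) > smaller


def grade_facts(grade_a: float, grade_b: float, third_grade: float | None = None) -> ReconciledGrade:
    """Reconcile two graders' fact sums (+1 per correct fact, -1 per incorrect).

    Agreement (divergence <= 100%) -> mean of the two grades.  Divergence ->
    the third grader's score is final; if none was supplied the result is an
    explicit escalation, not a number.
    """
    if not grades_diverge(grade_a, grade_b):
        return ReconciledGrade(value=(grade_a + grade_b) / 2.0)
    if third_grade is None:
        return ReconciledGrade(value=None, needs_third=True)
    return ReconciledGrade(value=float(third_grade), needs_third=True, used_third=True)


def make_grading_sheets(
    records: Sequence[ParticipantRecord], topic: str, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Blinded grading sheets for two graders plus the answer key.

    Each sheet lists (sheet_row, fact text) with the row order shuffled
    independently per grader and no condition information; the key maps
    sheet rows back to (participant, line).  The shuffle seed is recorded in
    the key's attrs so grading is reproducible.
    """
    rows = [
        {"participant_id": rec.participant_id, "line": i, "fact": ln}
        for rec in records
        for i, ln in enumerate(rec.recall.get(topic, []))
        if ln.strip()
    ]
    key = pd.DataFrame(rows, columns=["participant_id", "line", "fact"])
    key.attrs["seed"] = seed
    key.attrs["topic"] = topic
    rng = np.random.default_rng(seed)
    sheets = []
    for _ in range(2):
        order = rng.permutation(len(key))
        sheet = key.loc[order, ["fact"]].reset_index().rename(columns={"index": "key_row"})
        sheets.append(sheet)
    return sheets[0], sheets[1], key


# ---------------------------------------------------------------------------
# omnibus statistics


def scores_long(
    records: Sequence[ParticipantRecord], metric: str = "understanding"
) -> pd.DataFrame:
    """Long-form per-observation table (participant, topic, version, score)."""
    scorer = understanding_score if metric == "understanding" else learning_score
    rows = []
    for rec in records:
        for topic in TOPICS:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "topic": topic,
                    "version": rec.version_for(topic),
                    "score": scorer(rec, topic),
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(
    values: Sequence[float], version: Sequence[str], topic: Sequence[str]
) -> dict[str, StatResult]:
    """Fixed-effects 2x2 ANOVA with interaction (Type-I sums of squares).

    On balanced data Type-I equals every other type.  Requires at least two
    observations in every cell; zero residual variance is flagged, not
    reported as an F value.
    """
    frame = pd.DataFrame({"score": values, "version": version, "topic": topic})
    counts = frame.groupby(["version", "topic"], observed=True).size()
    for v in VERSIONS:
        for t in TOPICS:
            if counts.get((v, t), 0) < 2:
                raise ValueError(f"cell (version={v}, topic={t}) has fewer than 2 observations")
    model = smf.ols("score ~ C(version) * C(topic)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=1)
    df_resid = float(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"]) / df_resid
    # treat floating-point residue on (near-)constant data as zero variance
    scale = float(np.mean(np.square(frame["score"])))
    if mse <= 1e-12 * max(scale, 1.0):
        mse = 0.0
    effects = {
        "version": "C(version)",
        "topic": "C(topic)",
        "interaction": "C(version):C(topic)",
    }
    out: dict[str, StatResult] = {}
    for name, row in effects.items():
        df_num = float(table.loc[row, "df"])
        if mse == 0.0:
            out[name] = StatResult(
                kind="F", statistic=None, df=(df_num, df_resid), p_value=None,
                note="zero residual variance",
            )
            continue
        out[name] = StatResult(
            kind="F",
            statistic=float(table.loc[row, "F"]),
            df=(df_num, df_resid),
            p_value=float(table.loc[row, "PR(>F)"]),
        )
    # direction labels for the main effects
    for name, col in (("version", "version"), ("topic", "topic")):
        if out[name].defined:
            means = frame.groupby(col, observed=True)["score"].mean()
            out[name].direction = f"higher for {means.idxmax()}"
    return out


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson results: r, two-tailed p, and n per cell."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def result(self, a: str, b: str) -> StatResult:
        r = self.r.loc[a, b]
        if pd.isna(r):
            return StatResult(kind="r", statistic=None, df=None, p_value=None, note="undefined (zero variance or n < 3)")
        n = int(self.n.loc[a, b])
        return StatResult(kind="r", statistic=float(r), df=float(n - 2), p_value=float(self.p.loc[a, b]))


def correlation_analysis(frame: pd.DataFrame, columns: Sequence[str] | None = None) -> CorrelationMatrix:
    """Two-tailed Pearson correlations over participant-level score columns.

    Missing data are dropped pairwise; cells with fewer than 3 complete
    pairs or a zero-variance column are undefined (NaN r, flagged via
    :meth:`CorrelationMatrix.result`).
    """
    columns = list(columns) if columns is not None else [c for c in frame.columns if frame[c].dtype.kind in "fiu"]
    k = len(columns)
    r = pd.DataFrame(np.full((k, k), np.nan), index=columns, columns=columns)
    p = r.copy()
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for j, b in enumerate(columns):
            if i == j:
                col = frame[a].dropna()
                n.loc[a, b] = len(col)
                if len(col) >= 2 and col.std(ddof=1) > 0:
                    r.loc[a, b] = 1.0
                    p.loc[a, b] = 0.0
                continue
            pair = frame[[a, b]].dropna()
            n.loc[a, b] = len(pair)
            if len(pair) < 3 or pair[a].std(ddof=1) == 0 or pair[b].std(ddof=1) == 0:
                continue
            rr, pp = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b] = rr
            p.loc[a, b] = pp
    return CorrelationMatrix(r=r, p=p, n=n)


def participant_scores(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """One row per participant: pooled metric scores plus covariates.

    Understanding and learning are each participant's mean over their two
    topics; retention counts are summed over topics; perceived difficulty is
    split by version.  This is the table the correlation analysis runs on.
    """
    rows = []
    for rec in records:
        facts = words = unique = 0
        for topic in TOPICS:
            f, w, u = retention_counts(rec, topic)
            facts, words, unique = facts + f, words + w, unique + u
        rows.append(
            {
                "participant_id": rec.participant_id,
                "understanding": float(np.mean([understanding_score(rec, t) for t in TOPICS])),
                "learning": float(np.mean([learning_score(rec, t) for t in TOPICS])),
                "facts": facts,
                "words": words,
                "unique_words": unique,
                "perceived_original": float(np.mean(rec.likert["original"])),
                "perceived_simplified": float(np.mean(rec.likert["simplified"])),
                **{k: float(v) for k, v in rec.covariates.items()},
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def metric_means_by_version(records: Sequence[ParticipantRecord], metric: str) -> dict[str, float]:
    """Cohort mean of a metric per version (each participant contributes one
    observation to each version, from the topic they saw in that version)."""
    frame = scores_long(records, metric)
    return frame.groupby("version", observed=True)["score"].mean().to_dict()


# ---------------------------------------------------------------------------
# response-table I/O (schema documented in docs/response-schema.md)

_RECALL_SEP = " | "


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records to the one-row-per-participant CSV schema."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "participant_id": rec.participant_id,
            "first_topic": rec.first_topic,
            "first_version": rec.first_version,
        }
        for k, v in rec.covariates.items():
            row[k] = v
        for i, q in enumerate(rec.qualifiers, start=1):
            row[f"qual_{i}"] = int(q)
        for version in VERSIONS:
            for i, s in enumerate(rec.likert[version], start=1):
                row[f"likert_{version}_{i}"] = s
        for topic in TOPICS:
            for i, f in enumerate(rec.mc_pre[topic], start=1):
                row[f"{topic}_pre_{i}"] = int(bool(f))
            for i, f in enumerate(rec.mc_during[topic], start=1):
                row[f"{topic}_during_{i}"] = int(bool(f))
            for i, f in enumerate(rec.mc_post[topic], start=1):
                row[f"{topic}_post_{i}"] = int(bool(f))
            row[f"recall_{topic}"] = _RECALL_SEP.join(rec.recall.get(topic, []))
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Inverse of :func:`records_to_frame`."""
    covariate_cols = [
        c for c in ("education", "language", "stress", "health_literacy") if c in frame.columns
    ]
    qual_cols = sorted(
        (c for c in frame.columns if c.startswith("qual_")), key=lambda c: int(c.split("_")[1])
    )
    records = []
    for _, row in frame.iterrows():
        recall = {}
        for topic in TOPICS:
            raw = row.get(f"recall_{topic}", "")
            raw = "" if pd.isna(raw) else str(raw)
            recall[topic] = [ln for ln in raw.split(_RECALL_SEP) if ln] if raw else []
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                first_topic=str(row["first_topic"]),
                first_version=str(row["first_version"]),
                qualifiers=[bool(int(row[c])) for c in qual_cols],
                likert={
                    v: [int(row[f"likert_{v}_{i}"]) for i in range(1, N_SNIPPETS + 1)]
                    for v in VERSIONS
                },
                mc_pre={
                    t: [bool(int(row[f"{t}_pre_{i}"])) for i in range(1, N_LEARNING + 1)]
                    for t in TOPICS
                },
                mc_during={
                    t: [bool(int(row[f"{t}_during_{i}"])) for i in range(1, N_UNDERSTANDING + 1)]
                    for t in TOPICS
                },
                mc_post={
                    t: [bool(int(row[f"{t}_post_{i}"])) for i in range(1, N_LEARNING + 1)]
                    for t in TOPICS
                },
                recall=recall,
                covariates={c: float(row[c]) for c in covariate_cols},
            )
        )
    return records
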
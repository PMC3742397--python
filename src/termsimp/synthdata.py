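"""Synthetic fixtures and study simulation with known ground truth.

Nothing in the pipeline can ship its real inputs: the web-corpus frequency
table, the thesaurus/terminology dumps, and the reader-study response data
are all licensed or private.  This module generates structural stand-ins —
frequency tables with a controlled number of terms above and below the
difficulty threshold, resource files with at least one alternative per hard
term, and balanced 2x2 study cohorts whose correctness probabilities, Likert
means, and covariate effects are configured, so every estimator in
:mod:`termsimp.study_eval` can be checked against the value it was generated
from.

The study generator's defaults are the observed aggregates of the reader
study it emulates: understanding 52% (original) vs 63% (simplified),
learning gains of 9 vs 18 percentage points, perceived difficulty 3.2 vs
2.3 on the 5-point scale, 105 completers of whom 6 fail an attention check,
and a positive education-understanding correlation of about 0.25.  Two
generator parameters need calibration so the estimators are unbiased for
the configured values: the Likert location parameter is solved so the
*discretized* truncated-normal mean equals the target, and the per-SD
education shift on answer probabilities is solved so the induced Pearson r
on the pooled understanding score equals the target (binomial noise
attenuates a naive shift; the derivation is in the methods note).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from termsimp.study_eval import (
    N_LEARNING,
    N_SNIPPETS,
    N_UNDERSTANDING,
    TOPICS,
    VERSIONS,
    ParticipantRecord,
    other_topic,
    other_version,
    records_to_frame,
)

# the four balanced condition patterns, cycled over participants
CONDITION_PATTERNS: tuple[tuple[str, str], ...] = (
    ("asthma", "original"),
    ("asthma", "simplified"),
    ("cirrhosis", "original"),
    ("cirrhosis", "simplified"),
)

# ordinal covariate marginals (probability per code, low to high)
EDUCATION_LEVELS = (1, 2, 3, 4, 5, 6)
EDUCATION_PROBS = (1 / 99, 48 / 99, 16 / 99, 25 / 99, 6 / 99, 3 / 99)
LANGUAGE_LEVELS = (1, 2, 3, 4, 5)
LANGUAGE_PROBS = (0.0, 1 / 99, 3 / 99, 6 / 99, 89 / 99)

# closed-vocabulary recall templates; false ones state common myths
RECALL_FACTS: dict[str, dict[str, tuple[str, ...]]] = {
    "asthma": {
        "true": (
            "asthma narrows the airways",
            "inhalers relax airway muscles",
            "asthma causes wheezing and coughing",
            "attacks can be triggered by allergens",
            "asthma is a chronic lung condition",
            "exercise can trigger symptoms",
            "inflammation swells the airway lining",
            "asthma severity varies over time",
        ),
        "false": (
            "asthma is contagious",
            "people outgrow asthma completely",
            "inhalers are addictive",
            "asthma is only a childhood illness",
        ),
    },
    "cirrhosis": {
        "true": (
            "cirrhosis scars the liver",
            "heavy drinking can cause cirrhosis",
            "hepatitis can lead to cirrhosis",
            "scar tissue replaces healthy liver cells",
            "cirrhosis develops slowly over years",
            "the liver filters toxins from blood",
            "advanced cirrhosis can cause jaundice",
            "liver damage from cirrhosis is permanent",
        ),
        "false": (
            "only alcoholics get cirrhosis",
            "the liver always regrows fully",
            "cirrhosis is curable with vitamins",
            "cirrhosis only affects old people",
        ),
    },
}


@dataclass
class StudyGeneratorConfig:
    """Generator parameters; defaults are the emulated study's aggregates.

    Probabilities are per-question success rates; ``*_p`` dicts are keyed by
    version (and topic where the design crosses them).  ``seed`` is
    mandatory — every draw flows from it.
    """

    seed: int
    n_participants: int = 105
    qualifier_failures: int = 6
    n_qualifiers: int = 4
    understanding_p: dict[str, float] = field(
        default_factory=lambda: {"original": 0.52, "simplified": 0.63}
    )
    #: asthma-minus-cirrhosis shift in understanding probability (the study
    #: found asthma easier; the magnitude is this package's choice)
    understanding_topic_delta: float = 0.08
    learning_pre_p: float = 0.35
    #: post-reading probability per version (gains of 9 and 18 points)
    learning_post_p: dict[str, float] = field(
        default_factory=lambda: {"original": 0.44, "simplified": 0.53}
    )
    #: cirrhosis-minus-asthma shift in learning gain, in probability units
    #: (the study: 20 vs 6 points of gain by topic)
    learning_topic_delta: float = 0.14
    likert_mean: dict[str, float] = field(
        default_factory=lambda: {"original": 3.2, "simplified": 2.3}
    )
    likert_sd: float = 1.0
    recall_facts_mean: dict[str, float] = field(
        default_factory=lambda: {"original": 4.66, "simplified": 5.04}
    )
    #: fraction of recalled lines that state an incorrect fact
    recall_false_rate: float = 0.05
    education_understanding_r: float = 0.25
    language_stress_r: float = -0.21
    stress_mean: float = 16.0
    stress_sd: float = 6.0
    health_literacy_mean: float = 32.0
    health_literacy_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants for a balanced design")
        for p in (
            *self.understanding_p.values(),
            self.learning_pre_p,
            *self.learning_post_p.values(),
            self.recall_false_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0 <= self.qualifier_failures <= self.n_participants:
            raise ValueError("qualifier_failures outside [0, n_participants]")

    def understanding_cell_p(self, version: str, topic: str) -> float:
        shift = self.understanding_topic_delta / 2.0
        return self.understanding_p[version] + (shift if topic == "asthma" else -shift)

    def learning_post_cell_p(self, version: str, topic: str) -> float:
        shift = self.learning_topic_delta / 2.0
        return self.learning_post_p[version] + (-shift if topic == "asthma" else shift)


@dataclass
class StudySimulation:
    """Generated cohort plus the ground truth it was drawn from."""

    records: list[ParticipantRecord]
    config: StudyGeneratorConfig
    #: per (participant, topic): how many recalled lines were true/false facts
    recall_truth: pd.DataFrame

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


# ---------------------------------------------------------------------------
# calibration


@lru_cache(maxsize=None)
def discretized_likert_mu(target_mean: float, sd: float) -> float:
    """Location mu such that round-and-clip of N(mu, sd) to {1..5} has the target mean.

    Bin probabilities are exact normal CDF differences, so the solved mu
    makes the generator's Likert mean unbiased for the configured value.
    """
    if not 1.0 < target_mean < 5.0:
        raise ValueError("target Likert mean must be inside (1, 5)")

    def mean_at(mu: float) -> float:
        edges = np.array([1.5, 2.5, 3.5, 4.5])
        cdf = norm.cdf((edges - mu) / sd)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(np.dot(np.arange(1, 6), probs))

    return float(optimize.brentq(lambda mu: mean_at(mu) - target_mean, -10.0, 15.0, xtol=1e-12))


def _covariate_moments(levels: Sequence[int], probs: Sequence[float]) -> tuple[float, float]:
    levels = np.asarray(levels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    mean = float(np.dot(levels, probs))
    var = float(np.dot(levels**2, probs) - mean**2)
    return mean, math.sqrt(var)


def education_shift_per_sd(config: StudyGeneratorConfig) -> float:
    """Per-SD-of-education shift in answer probability inducing the target r.

    For pooled understanding U = mean of two topic percentages with 5
    questions each, Bernoulli success p = p_cell + b*e (e standardized
    education), the induced correlation is

        r = 100 b / sqrt(500 S + 9000 b^2),   S = avg over patterns of
                                                  sum of p_cell (1 - p_cell)

    solved for b in closed form.  Attenuation by the binomial question noise
    is what makes b smaller than a naive r * sd ratio.
    """
    r = config.education_understanding_r
    if r == 0.0:
        return 0.0
    patterns_s = []
    for first_topic, first_version in CONDITION_PATTERNS:
        s = 0.0
        for topic in TOPICS:
            version = first_version if topic == first_topic else other_version(first_version)
            p = config.understanding_cell_p(version, topic)
            s += p * (1.0 - p)
        patterns_s.append(s)
    s_avg = float(np.mean(patterns_s))
    denom = 10_000.0 - 9_000.0 * r * r
    if denom <= 0:
        raise ValueError("target education-understanding r too large to induce")
    return math.copysign(math.sqrt(r * r * 500.0 * s_avg / denom), r)


# ---------------------------------------------------------------------------
# study simulation


def _draw_ordinal(rng: np.random.Generator, z: np.ndarray, probs: Sequence[float], levels: Sequence[int]) -> np.ndarray:
    """Map latent standard-normal draws to ordinal codes by quantile thresholds."""
    cum = np.cumsum(np.asarray(probs, dtype=float))[:-1]
    thresholds = norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    return np.asarray(levels)[np.searchsorted(thresholds, z)]


def simulate_study(config: StudyGeneratorConfig) -> StudySimulation:
    """Draw a full synthetic cohort; deterministic under ``config.seed``.

    Condition assignment cycles the four (first topic, first version)
    patterns in participant order, so any n divisible by 4 is exactly
    balanced and a remainder is spread round-robin.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    b = education_shift_per_sd(config)
    edu_mean, edu_sd = _covariate_moments(EDUCATION_LEVELS, EDUCATION_PROBS)
    likert_mu = {
        v: discretized_likert_mu(config.likert_mean[v], config.likert_sd) for v in VERSIONS
    }

    # latent covariates: language and stress share a configured correlation
    z_edu = rng.standard_normal(n)
    z_lang = rng.standard_normal(n)
    rho = config.language_stress_r
    z_stress = rho * z_lang + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(n)
    z_lit = rng.standard_normal(n)

    education = _draw_ordinal(rng, z_edu, EDUCATION_PROBS, EDUCATION_LEVELS)
    language = _draw_ordinal(rng, z_lang, LANGUAGE_PROBS, LANGUAGE_LEVELS)
    stress = np.clip(np.rint(config.stress_mean + config.stress_sd * z_stress), 0, 40).astype(int)
    literacy = np.clip(
        np.rint(config.health_literacy_mean + config.health_literacy_sd * z_lit), 0, 36
    ).astype(int)

    failing = set(
        rng.choice(n, size=config.qualifier_failures, replace=False).tolist()
        if config.qualifier_failures
        else []
    )

    records: list[ParticipantRecord] = []
    truth_rows: list[dict[str, object]] = []
    for i in range(n):
        first_topic, first_version = CONDITION_PATTERNS[i % 4]
        pid = f"p{i + 1:03d}"
        e_std = (education[i] - edu_mean) / edu_sd

        qualifiers = [True] * config.n_qualifiers
        if i in failing:
            qualifiers[int(rng.integers(config.n_qualifiers))] = False

        likert = {
            v: np.clip(
                np.rint(rng.normal(likert_mu[v], config.likert_sd, size=N_SNIPPETS)), 1, 5
            ).astype(int).tolist()
            for v in VERSIONS
        }

        mc_pre: dict[str, list[bool]] = {}
        mc_during: dict[str, list[bool]] = {}
        mc_post: dict[str, list[bool]] = {}
        recall: dict[str, list[str]] = {}
        for topic in TOPICS:
            version = first_version if topic == first_topic else other_version(first_version)
            p_und = float(np.clip(config.understanding_cell_p(version, topic) + b * e_std, 0.01, 0.99))
            mc_during[topic] = (rng.random(N_UNDERSTANDING) < p_und).tolist()
            mc_pre[topic] = (rng.random(N_LEARNING) < config.learning_pre_p).tolist()
            p_post = config.learning_post_cell_p(version, topic)
            mc_post[topic] = (rng.random(N_LEARNING) < p_post).tolist()

            n_facts = int(rng.poisson(config.recall_facts_mean[version]))
            lines: list[str] = []
            n_false = 0
            for _ in range(n_facts):
                is_false = rng.random() < config.recall_false_rate
                pool = RECALL_FACTS[topic]["false" if is_false else "true"]
                lines.append(pool[int(rng.integers(len(pool)))])
                n_false += int(is_false)
            recall[topic] = lines
            truth_rows.append(
                {
                    "participant_id": pid,
                    "topic": topic,
                    "version": version,
                    "n_facts": n_facts,
                    "n_true": n_facts - n_false,
                    "n_false": n_false,
                }
            )

        records.append(
            ParticipantRecord(
                participant_id=pid,
                first_topic=first_topic,
                first_version=first_version,
                qualifiers=qualifiers,
                likert=likert,
                mc_pre=mc_pre,
                mc_during=mc_during,
                mc_post=mc_post,
                recall=recall,
                covariates={
                    "education": float(education[i]),
                    "language": float(language[i]),
                    "stress": float(stress[i]),
                    "health_literacy": float(literacy[i]),
                },
            )
        )

    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "topic", "version", "n_facts", "n_true", "n_false"]
    )
    return StudySimulation(records=records, config=config, recall_truth=truth)


def write_study(sim: StudySimulation, out_dir: str | Path) -> dict[str, Path]:
    """Write responses.csv, recall_truth.csv, and truth.json under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": out_dir / "responses.csv",
        "recall_truth": out_dir / "recall_truth.csv",
        "truth": out_dir / "truth.json",
    }
    sim.frame.to_csv(paths["responses"], index=False)
    sim.recall_truth.to_csv(paths["recall_truth"], index=False)
    paths["truth"].write_text(json.dumps(asdict(sim.config), indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# lexicon fixtures

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudoword(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        _CONSONANTS[int(rng.integers(len(_CONSONANTS)))] + _VOWELS[int(rng.integers(len(_VOWELS)))]
        for _ in range(n_syllables)
    )


@dataclass
class LexiconFixture:
    """Generated frequency table, resource file, and tagger table (as text/dict)."""

    frequency_tsv: str
    resource_tsv: str
    tagger: dict[str, str]
    easy_terms: list[str]
    hard_terms: list[str]
    threshold: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "frequency": out_dir / "frequency.tsv",
            "resources": out_dir / "resources.tsv",
            "tagger": out_dir / "tagger.tsv",
        }
        paths["frequency"].write_text(self.frequency_tsv, encoding="utf-8")
        paths["resources"].write_text(self.resource_tsv, encoding="utf-8")
        paths["tagger"].write_text(
            "".join(f"{w}\t{t}\n" for w, t in self.tagger.items()), encoding="utf-8"
        )
        return paths


def make_lexicon_fixture(n_easy: int, n_hard: int, threshold: int, seed: int) -> LexiconFixture:
    """Pseudoword lexicon with exactly ``n_hard`` terms below the threshold.

    Every hard term gets at least one resource entry: a same-POS synonym
    pointing at an easy (above-threshold) word when one exists, plus a short
    lay definition, so the candidate pipeline always has something to rank.
    Deterministic under ``seed`` (byte-identical files).
    """
    if n_easy < 0 or n_hard < 0:
        raise ValueError("term counts must be >= 0")
    rng = np.random.default_rng(seed)
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n_easy + n_hard:
        w = _pseudoword(rng)
        if w not in seen:
            seen.add(w)
            words.append(w)
    easy, hard = words[:n_easy], words[n_easy : n_easy + n_hard]

    counts: dict[str, int] = {}
    hi = max(threshold * 10, threshold + 10)
    for w in easy:
        counts[w] = int(rng.integers(threshold, hi))
    for w in hard:
        counts[w] = int(rng.integers(0, max(threshold, 1)))

    tagger = {w: "noun" for w in words}

    freq_lines = [f"{w}\t{counts[w]}\n" for w in easy + hard]
    res_lines: list[str] = []
    for i, w in enumerate(hard):
        if easy:
            partner = easy[i % len(easy)]
            res_lines.append(f"{w}\tnoun\tsynonym\twordnet\t{partner}\n")
        res_lines.append(f"{w}\tnoun\tdefinition\twiktionary_simple\ta common everyday thing\n")

    return LexiconFixture(
        frequency_tsv="".join(freq_lines),
        resource_tsv="".join(res_lines),
        tagger=tagger,
        easy_terms=easy,
        hard_terms=hard,
        threshold=threshold,
    )
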
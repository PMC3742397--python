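"""Metric families, grading reconciliation, and the omnibus statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from termsimp import study_eval as se
from termsimp.study_eval import (
    ParticipantRecord,
    correlation_analysis,
    filter_qualifying,
    grade_facts,
    grades_diverge,
    learning_score,
    paired_ttest,
    perceived_difficulty,
    retention_counts,
    two_way_anova,
    understanding_score,
)


def make_record(
    pid="p1",
    first_topic="asthma",
    first_version="original",
    qualifiers=(True, True, True),
    likert_original=(3, 3, 3, 3, 3),
    likert_simplified=(2, 2, 2, 2, 2),
    during=None,
    pre=None,
    post=None,
    recall=None,
    covariates=None,
) -> ParticipantRecord:
    during = during or {t: [True] * 5 for t in se.TOPICS}
    pre = pre or {t: [False] * 7 for t in se.TOPICS}
    post = post or {t: [True] * 7 for t in se.TOPICS}
    return ParticipantRecord(
        participant_id=pid,
        first_topic=first_topic,
        first_version=first_version,
        qualifiers=list(qualifiers),
        likert={"original": list(likert_original), "simplified": list(likert_simplified)},
        mc_pre=pre,
        mc_during=during,
        mc_post=post,
        recall=recall or {t: [] for t in se.TOPICS},
        covariates=covariates or {},
    )


class TestFilterQualifying:
    def test_all_true_kept(self):
        kept, dropped = filter_qualifying([make_record()])
        assert len(kept) == 1 and dropped == []

    def test_one_false_dropped(self):
        kept, dropped = filter_qualifying([make_record(qualifiers=(True, False, True))])
        assert kept == [] and dropped == ["p1"]

    def test_mixed_cohort_counts(self):
        records = [make_record(pid=f"p{i}") for i in range(10)]
        records[3].qualifiers[0] = False
        records[7].qualifiers[2] = False
        kept, dropped = filter_qualifying(records)
        assert len(kept) == 8 and sorted(dropped) == ["p3", "p7"]


class TestPerceivedDifficulty:
    def test_degenerate_identical_scores_flagged(self):
        records = [make_record(pid=f"p{i}", likert_original=(3,) * 5, likert_simplified=(3,) * 5) for i in range(4)]
        result = perceived_difficulty(records)
        assert result.pooled_means == {"original": 3.0, "simplified": 3.0}
        assert result.ttest.statistic is None
        assert result.ttest.p_value is None
        assert result.ttest.note is not None

    def test_three_participant_t_matches_hand_formula(self):
        # per-participant mean differences: 1.0, 0.6, 0.2
        records = [
            make_record(pid="a", likert_original=(4, 4, 4, 4, 4), likert_simplified=(3, 3, 3, 3, 3)),
            make_record(pid="b", likert_original=(4, 3, 4, 3, 4), likert_simplified=(3, 3, 3, 3, 3)),
            make_record(pid="c", likert_original=(3, 3, 3, 3, 4), likert_simplified=(3, 3, 3, 3, 3)),
        ]
        result = perceived_difficulty(records)
        d = np.array([1.0, 0.6, 0.2])
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert result.ttest.statistic == pytest.approx(t_hand)
        assert result.ttest.df == 2
        assert result.ttest.direction == "original harder"

    def test_per_sentence_means_shape(self):
        result = perceived_difficulty([make_record()])
        assert list(result.per_sentence_means.columns) == ["original", "simplified"]
        assert len(result.per_sentence_means) == 5


class TestScores:
    def test_understanding_all_correct(self):
        assert understanding_score(make_record(), "asthma") == 100.0

    def test_understanding_three_of_five(self):
        rec = make_record(during={t: [True, True, True, False, False] for t in se.TOPICS})
        assert understanding_score(rec, "asthma") == 60.0

    def test_learning_two_to_four(self):
        rec = make_record(
            pre={t: [True, True, False, False, False, False, False] for t in se.TOPICS},
            post={t: [True, True, True, True, False, False, False] for t in se.TOPICS},
        )
        assert learning_score(rec, "cirrhosis") == pytest.approx(100 * 2 / 7)

    def test_learning_no_change_is_zero(self):
        flags = {t: [True, False, True, False, True, False, True] for t in se.TOPICS}
        rec = make_record(pre=flags, post={t: list(v) for t, v in flags.items()})
        assert learning_score(rec, "asthma") == 0.0

    def test_scores_bounded(self):
        rec = make_record(
            pre={t: [True] * 7 for t in se.TOPICS}, post={t: [False] * 7 for t in se.TOPICS}
        )
        assert learning_score(rec, "asthma") == pytest.approx(-100.0)
        assert 0 <= understanding_score(rec, "asthma") <= 100


class TestRetention:
    def test_no_lines(self):
        assert retention_counts(make_record(), "asthma") == (0, 0, 0)

    def test_hand_counts(self):
        rec = make_record(recall={"asthma": ["asthma narrows airways", "inhalers help"], "cirrhosis": []})
        assert retention_counts(rec, "asthma") == (2, 5, 5)

    def test_duplicate_line_changes_facts_not_unique_words(self):
        once = make_record(recall={"asthma": ["inhalers help"], "cirrhosis": []})
        twice = make_record(recall={"asthma": ["inhalers help", "inhalers help"], "cirrhosis": []})
        f1, _, u1 = retention_counts(once, "asthma")
        f2, _, u2 = retention_counts(twice, "asthma")
        assert (f1, f2) == (1, 2)
        assert u1 == u2

    def test_blank_lines_ignored(self):
        rec = make_record(recall={"asthma": ["", "  ", "one fact"], "cirrhosis": []})
        assert retention_counts(rec, "asthma")[0] == 1


def oracle_diverge(a: float, b: float) -> bool:
    """Literal reading of the rule: disagreement exceeding 100% of the smaller score."""
    if a == b:
        return False
    smaller = min(abs(a), abs(b))
    return True if smaller == 0 else abs(a - b) / smaller > 1.0


class TestGrading:
    def test_agreement_returns_value(self):
        assert grade_facts(4, 4).value == 4

    def test_divergent_pair_needs_third(self):
        outcome = grade_facts(2, 5)
        assert outcome.needs_third and outcome.value is None
        resolved = grade_facts(2, 5, third_grade=4)
        assert resolved.value == 4 and resolved.used_third

    def test_four_correct_one_incorrect_scores_three(self):
        # +1 per correct fact, -1 per incorrect: a grader sums 4 - 1 = 3
        assert 4 * (+1) + 1 * (-1) == 3
        assert grade_facts(3, 3).value == 3

    def test_mild_disagreement_takes_mean(self):
        assert grade_facts(4, 6).value == 5.0

    @pytest.mark.parametrize("a,b", list(itertools.product(range(-5, 6), repeat=2)))
    def test_divergence_rule_matches_oracle_on_grid(self, a, b):
        assert grades_diverge(a, b) == oracle_diverge(a, b)
        outcome = grade_facts(a, b, third_grade=0)
        if oracle_diverge(a, b):
            assert outcome.used_third and outcome.value == 0
        else:
            assert outcome.value == (a + b) / 2

    def test_grading_sheets_blind_and_keyed(self):
        records = [
            make_record(pid="p1", recall={"asthma": ["fact one"], "cirrhosis": []}),
            make_record(pid="p2", recall={"asthma": ["fact two", "fact three"], "cirrhosis": []}),
        ]
        sheet_a, sheet_b, key = se.make_grading_sheets(records, "asthma", seed=3)
        assert set(sheet_a["fact"]) == {"fact one", "fact two", "fact three"}
        assert "participant_id" not in sheet_a.columns  # blinded
        assert len(key) == 3 and key.attrs["seed"] == 3
        # key rows resolve every sheet row
        assert set(sheet_a["key_row"]) == set(key.index)


BALANCED_CELLS = {
    ("original", "asthma"): [40, 60],
    ("original", "cirrhosis"): [50, 70],
    ("simplified", "asthma"): [60, 80],
    ("simplified", "cirrhosis"): [70, 90],
}


def hand_anova(cells):
    """Independent sums-of-squares oracle for a balanced 2x2 design."""
    data = [(v, t, x) for (v, t), xs in cells.items() for x in xs]
    values = np.array([x for _, _, x in data], dtype=float)
    grand = values.mean()
    n_cell = {k: len(v) for k, v in cells.items()}
    versions = sorted({v for v, _ in cells})
    topics = sorted({t for _, t in cells})
    v_mean = {v: np.mean([x for vv, _, x in data if vv == v]) for v in versions}
    t_mean = {t: np.mean([x for _, tt, x in data if tt == t]) for t in topics}
    c_mean = {k: np.mean(v) for k, v in cells.items()}
    ss_a = sum(len([1 for vv, *_ in data if vv == v]) * (v_mean[v] - grand) ** 2 for v in versions)
    ss_b = sum(len([1 for _, tt, _ in data if tt == t]) * (t_mean[t] - grand) ** 2 for t in topics)
    ss_ab = sum(
        n_cell[(v, t)] * (c_mean[(v, t)] - v_mean[v] - t_mean[t] + grand) ** 2
        for v in versions
        for t in topics
    )
    ss_err = sum((x - c_mean[(v, t)]) ** 2 for v, t, x in data)
    df_err = len(data) - len(cells)
    mse = ss_err / df_err
    return {
        "version": ss_a / mse,
        "topic": ss_b / mse,
        "interaction": ss_ab / mse,
        "ss": (ss_a, ss_b, ss_ab, ss_err),
        "df_err": df_err,
    }


def cells_to_columns(cells):
    values, version, topic = [], [], []
    for (v, t), xs in cells.items():
        for x in xs:
            values.append(x)
            version.append(v)
            topic.append(t)
    return values, version, topic


class TestAnova:
    def test_hand_example(self):
        result = two_way_anova(*cells_to_columns(BALANCED_CELLS))
        assert result["version"].statistic == pytest.approx(4.0, abs=1e-9)
        assert result["topic"].statistic == pytest.approx(1.0, abs=1e-9)
        assert result["interaction"].statistic == pytest.approx(0.0, abs=1e-9)
        assert result["version"].df == (1.0, 4.0)
        assert result["version"].direction == "higher for simplified"

    def test_all_equal_observations_flagged(self):
        cells = {k: [50, 50] for k in BALANCED_CELLS}
        result = two_way_anova(*cells_to_columns(cells))
        for res in result.values():
            assert res.statistic is None
            assert res.note == "zero residual variance"

    def test_empty_cell_raises_with_name(self):
        cells = dict(BALANCED_CELLS)
        cells[("simplified", "cirrhosis")] = [70]
        with pytest.raises(ValueError, match="simplified.*cirrhosis"):
            two_way_anova(*cells_to_columns(cells))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ss_conservation_and_oracle_match_on_random_balanced_designs(self, seed):
        rng = np.random.default_rng(seed)
        cells = {k: rng.normal(60, 15, size=6).round(2).tolist() for k in BALANCED_CELLS}
        hand = hand_anova(cells)
        result = two_way_anova(*cells_to_columns(cells))
        for effect in ("version", "topic", "interaction"):
            assert result[effect].statistic == pytest.approx(hand[effect], rel=1e-9)
        # SS conservation: components add to the total sum of squares
        values = np.array([x for xs in cells.values() for x in xs])
        ss_total = ((values - values.mean()) ** 2).sum()
        assert sum(hand["ss"]) == pytest.approx(ss_total, rel=1e-9)


class TestCorrelation:
    def test_exactly_linear_pair(self):
        frame = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        corr = correlation_analysis(frame, ["x", "y"])
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.n.loc["x", "y"] == 4

    def test_hand_four_point_dataset(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        r_hand = float(((x - x.mean()) * (y - y.mean())).sum()
                       / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        corr = correlation_analysis(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert corr.r.loc["x", "y"] == pytest.approx(r_hand)
        result = corr.result("x", "y")
        assert result.defined and 0 <= result.p_value <= 1

    def test_zero_variance_column_flagged(self):
        frame = pd.DataFrame({"x": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        corr = correlation_analysis(frame, ["x", "flat"])
        result = corr.result("x", "flat")
        assert result.statistic is None and result.note is not None

    def test_pairwise_deletion_reports_n(self):
        frame = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, np.nan], "y": [2.0, 1, 4, np.nan, 5], "z": [1.0, 2, 3, 4, 5]}
        )
        corr = correlation_analysis(frame, ["x", "y", "z"])
        assert corr.n.loc["x", "y"] == 3
        assert corr.n.loc["x", "z"] == 4


class TestPairedTtestHelper:
    def test_known_difference_vector(self):
        d = [1.0, 2.0, 3.0, 4.0]
        result = paired_ttest(d)
        t_hand = np.mean(d) / (np.std(d, ddof=1) / 2)
        assert result.statistic == pytest.approx(t_hand)
        assert result.df == 3

    def test_single_pair_flagged(self):
        assert paired_ttest([1.0]).statistic is None


class TestRecordRoundTrip:
    def test_frame_round_trip_preserves_everything(self):
        records = [
            make_record(pid="p1", recall={"asthma": ["a fact", "b fact"], "cirrhosis": ["c"]},
                        covariates={"education": 3, "language": 5, "stress": 12, "health_literacy": 30}),
            make_record(pid="p2", first_topic="cirrhosis", first_version="simplified",
                        covariates={"education": 2, "language": 4, "stress": 20, "health_literacy": 25}),
        ]
        back = se.records_from_frame(se.records_to_frame(records))
        assert back == records

    def test_version_assignment_complementary(self):
        rec = make_record(first_topic="cirrhosis", first_version="simplified")
        assert rec.version_for("cirrhosis") == "simplified"
        assert rec.version_for("asthma") == "original"
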
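# Study response CSV schema

One row per participant. Produced by `termsimp-synth study` and consumed
by `termsimp-study score` (`termsimp.study_eval.records_from_frame`).

| column | type | meaning |
|---|---|---|
| `participant_id` | string | unique respondent id |
| `first_topic` | `asthma` \| `cirrhosis` | topic of the first study section |
| `first_version` | `original` \| `simplified` | version of the first section; the second section is the other topic in the other version |
| `education` | int code | highest education completed, ordinal, higher = more (1 = less than high school … 6 = doctorate) |
| `language` | int code | frequency of speaking English at home, ordinal, higher = more (1 = never … 5 = only English) |
| `stress` | int | stress-instrument total score (0–40) |
| `health_literacy` | int | health-literacy-instrument total score (0–36) |
| `qual_1` … `qual_4` | 0/1 | qualifying (attention-check) questions answered correctly; any 0 drops the participant |
| `likert_original_1` … `_5` | 1–5 | perceived difficulty of the five original snippets (1 = Very Easy, 5 = Very Hard) |
| `likert_simplified_1` … `_5` | 1–5 | same for the simplified snippets |
| `<topic>_pre_1` … `_7` | 0/1 | myth-question correctness before reading (`<topic>` ∈ `asthma`, `cirrhosis`) |
| `<topic>_during_1` … `_5` | 0/1 | with-text question correctness (understanding) |
| `<topic>_post_1` … `_7` | 0/1 | myth-question correctness after reading (learning = post − pre) |
| `recall_<topic>` | string | free-recall lines joined by `" | "`; empty string = nothing recalled |

The ground-truth sidecar written next to `responses.csv` contains
`truth.json` (the full generator configuration, including the seed) and
`recall_truth.csv` (per participant and topic: `n_facts`, `n_true`,
`n_false` — the known correct grade is `n_true − n_false`).
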
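"""The published gout snippet pair used as a worked example and regression anchor.

One sentence about gout, in its original encyclopedia wording and in the
lexically simplified wording a medical-librarian writer produced with the
tool's worksheet (synonym swaps such as "disorder" -> "disease", parenthesised
glosses for terms like "uric acid" kept as-is).  The pair is the only study
stimulus short enough to publish inline, and it anchors the readability and
pipeline tests: the original counts 32 words, the simplified 37.
"""

GOUT_ORIGINAL = (
    "Gout is a disorder of purine metabolism, and occurs when its final "
    "metabolite, uric acid, crystallizes in the form of monosodium urate, "
    "precipitating in joints, on tendons, and in the surrounding tissues."
)

GOUT_SIMPLIFIED = (
    "Gout is a disease of the processing of the chemical substance called "
    "purine, and occurs when its last chemical product (uric acid) makes "
    "crystals (monosodium urate), which collect in joints, on tendons, and "
    "in the surrounding tissues."
)
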
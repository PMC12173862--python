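"""Dietary knowledge index (DKI).

A nine-item knowledge battery in the style of the China Health and Nutrition
Survey: each item is answered "agree", "disagree" or "unknown"; a correct
answer scores 1, an incorrect or "unknown" answer scores 0.  The index is the
item sum, ranging 0-9.
"""

from __future__ import annotations

from typing import Sequence

N_ITEMS = 9

#: Correct answer per item ("agree" or "disagree").
DEFAULT_ANSWER_KEY: tuple[str, ...] = (
    "agree", "agree", "disagree", "agree", "disagree",
    "agree", "disagree", "agree", "agree",
)


def dietary_knowledge_index(
    responses: Sequence[str],
    answer_key: Sequence[str] = DEFAULT_ANSWER_KEY,
) -> int:
    """Score a knowledge battery: 1 per correct answer, 0 otherwise."""
    if len(responses) != len(answer_key):
        raise ValueError(
            f"expected {len(answer_key)} responses, got {len(responses)}"
        )
    valid = {"agree", "disagree", "unknown"}
    for r in responses:
        if r not in valid:
            raise ValueError(f"invalid response {r!r}")
    return sum(1 for r, k in zip(responses, answer_key) if r == k)
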
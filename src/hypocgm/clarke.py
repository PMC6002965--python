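"""Clarke hypoglycaemia-awareness questionnaire scoring.

The instrument's seven binary items each score 0 (aware) or 1 (reduced
awareness); a summed score of 4 or more classifies reduced awareness.
Questions 5 and 6 report the frequency of hypoglycaemia (< 3.5 mmol/l,
with and without symptoms) in categories, which are recoded to an
approximate episodes-per-month rate for the Poisson analyses:
1-3 per month -> 2; one per week -> 1 x 4 = 4; two or three per week ->
2.5 x 4 = 10; four or five per week -> 4.5 x 4 = 18; almost daily -> 25.

The exact item-to-question mapping of the modified instrument is left to
the caller: this module scores whatever seven binary items it is handed.
"""

from __future__ import annotations

from .errors import InputError
from .types import FREQUENCY_CATEGORIES, ClarkeResponse, ClarkeResult

#: Monthly-rate recoding of the Q5/Q6 frequency categories.
RECODE_MAP: dict[str, float] = {
    "none": 0.0,
    "1-3 per month": 2.0,
    "1 per week": 4.0,
    "2-3 per week": 10.0,
    "4-5 per week": 18.0,
    "almost daily": 25.0,
}

# Accept the spelled-out category wordings as aliases on read.
_ALIASES = {
    "never": "none",
    "1-3 episodes per month": "1-3 per month",
    "one episode per week": "1 per week",
    "two or three episodes per week": "2-3 per week",
    "four or five episodes per week": "4-5 per week",
    "almost daily episodes": "almost daily",
}


def canonical_category(category: str) -> str:
    """Normalise a Q5/Q6 frequency category to the closed vocabulary."""
    if not isinstance(category, str):
        raise InputError(f"frequency category must be a string, got {category!r}")
    cat = category.strip().lower().replace("–", "-")
    cat = _ALIASES.get(cat, cat)
    if cat not in FREQUENCY_CATEGORIES:
        raise InputError(
            f"unknown frequency category {category!r}; expected one of "
            f"{FREQUENCY_CATEGORIES}"
        )
    return cat


def recode_frequency(category: str) -> float:
    """Recode a Q5/Q6 frequency category to episodes per month."""
    return RECODE_MAP[canonical_category(category)]


def score_clarke(resp: ClarkeResponse) -> ClarkeResult:
    """Score a questionnaire response.

    Score = sum of the seven 0/1 items; reduced awareness iff score >= 4.
    Q3/Q4 indicators are true iff the respective annual count is >= 1.
    Missing or non-binary items raise; nothing is imputed.
    """
    items = list(resp.items)
    if len(items) != 7:
        raise InputError("expected exactly seven Clarke items")
    if any(i not in (0, 1) for i in items):
        raise InputError("Clarke items must all be 0 or 1")
    score = int(sum(items))
    return ClarkeResult(
        subject_id=resp.subject_id,
        score=score,
        reduced_awareness=score >= 4,
        q5_rate_per_month=recode_frequency(resp.q5_category),
        q6_rate_per_month=recode_frequency(resp.q6_category),
        q3_any_assistance=resp.q3_assistance_per_year >= 1,
        q4_any_unconscious=resp.q4_unconscious_per_year >= 1,
    )
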
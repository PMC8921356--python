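"""Reader-panel consensus: A/B/C/D answers to accept/reject labels.

Readers rate each predicted contour on an ordinal scale:

* **A** — adjust, clear major mistakes (worst)
* **B** — adjust, minor but clinically relevant mistakes
* **C** — accept, small but irrelevant mistakes
* **D** — accept, very accurate (best)

A and B dichotomize to *reject*, C and D to *accept*.  The per-slice
consensus is taken by majority vote on the dichotomized answers; the
reported consensus letter is the modal answer among readers in the
winning binary class, modal ties broken toward the more severe letter
(A over B, C over D).  Plain four-category majority vote can fail on
panels like (A, B, C); dichotomize-first guarantees a defined
accept/reject consensus for any odd panel and agrees with the plain
majority whenever one exists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ANSWER_LETTERS",
    "ConsensusTieError",
    "AnswerPanel",
    "ConsensusLabel",
    "dichotomize",
    "consensus",
]

ANSWER_LETTERS = ("A", "B", "C", "D")
_REJECT = frozenset({"A", "B"})


class ConsensusTieError(ValueError):
    """Raised when an even reader panel splits exactly half accept / half reject."""


def _check_answer(answer: str) -> str:
    if answer not in ANSWER_LETTERS:
        raise ValueError(f"invalid answer {answer!r}; expected one of {ANSWER_LETTERS}")
    return answer


@dataclass
class AnswerPanel:
    """All readers' answers for one slice."""

    slice_id: str
    answers: Sequence[str]

    def __post_init__(self) -> None:
        if len(self.answers) < 1:
            raise ValueError("panel needs at least one answer")
        self.answers = tuple(_check_answer(a) for a in self.answers)


@dataclass
class ConsensusLabel:
    """Per-slice consensus: accept/reject plus the 4-level consensus letter."""

    slice_id: str
    accepted: bool
    consensus_answer: str

    def __post_init__(self) -> None:
        _check_answer(self.consensus_answer)
        if self.accepted != (self.consensus_answer not in _REJECT):
            raise ValueError("accepted flag inconsistent with consensus answer")


def dichotomize(answer: str) -> bool:
    """True (accept) for C/D, False (reject) for A/B."""
    return _check_answer(answer) not in _REJECT


def consensus(panel: AnswerPanel) -> ConsensusLabel:
    """Majority-vote consensus for one panel.

    Raises :class:`ConsensusTieError` on an exact binary tie (possible
    only with an even reader count); ties are never resolved silently.
    """
    if not isinstance(panel, AnswerPanel):
        panel = AnswerPanel("", list(panel))
    n_accept = sum(dichotomize(a) for a in panel.answers)
    n_reject = len(panel.answers) - n_accept
    if n_accept == n_reject:
        raise ConsensusTieError(
            f"slice {panel.slice_id!r}: {n_accept} accept vs {n_reject} reject "
            "answers — no binary majority"
        )
    accepted = n_accept > n_reject
    winning = [a for a in panel.answers if dichotomize(a) == accepted]
    counts = Counter(winning)
    top = max(counts.values())
    # modal tie -> more severe letter; letters sort severity-first (A<B<C<D)
    letter = min(a for a, c in counts.items() if c == top)
    return ConsensusLabel(panel.slice_id, accepted, letter)
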
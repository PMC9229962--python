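"""Rule activation, weighted-centroid defuzzification, and motion decision.

Given the six label weights of each channel, a rule fires iff both of its
labels have nonzero weight; its firing strength is the minimum of the two
weights (Mamdani min-AND).  Because fuzzification leaves at most two labels
nonzero per channel, between one and four of the 36 rules fire per step.

The crisp score of each output state is the firing-strength-weighted average
of the fired rules' center values,

    score = sum_i m_i * w_i / sum_i m_i,

with w in {0.5, 1, 2} for Low/Med/High strength.  The denominator is the
same for all five states, so every score is a convex combination of center
values and lies in [0.5, 2].  The detected motion is the state with the
largest score; an exact tie keeps the previous decision when it is among the
tied states (temporal continuity), else takes the tied state earliest in the
fixed output order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FuzzymotionError
from .rulebase import Rule, RuleTable
from .vocab import FUZZY_LABELS, MOTION_STATES


@dataclass(frozen=True)
class Activation:
    """A fired rule with its firing strength m = min of the two label weights."""

    rule: Rule
    m: float

    def __post_init__(self) -> None:
        if not 0.0 < self.m <= 1.0:
            raise FuzzymotionError(f"firing strength must be in (0, 1], got {self.m}")


def activate(w1: np.ndarray, w2: np.ndarray, table: RuleTable) -> list[Activation]:
    """Fire every rule whose both labels have nonzero weight.

    ``w1`` and ``w2`` are six-element weight vectors for modules 1 and 2 in
    the fixed label order.  Weights are compared against zero exactly:
    fuzzification constructs them and never produces spurious tiny values.
    """
    acts: list[Activation] = []
    for i in np.flatnonzero(w1):
        for j in np.flatnonzero(w2):
            rule = table.rule_for(FUZZY_LABELS[i], FUZZY_LABELS[j])
            acts.append(Activation(rule, float(min(w1[i], w2[j]))))
    return acts


def defuzzify(activations: list[Activation]) -> np.ndarray:
    """Weighted-average score per output state (order of ``MOTION_STATES``).

    An empty activation list signals an upstream invariant violation (a
    valid weight vector always fires at least one rule) and is rejected
    rather than silently mapped to rest.
    """
    if not activations:
        raise FuzzymotionError("cannot defuzzify an empty activation list")
    num = np.zeros(len(MOTION_STATES))
    den = 0.0
    for act in activations:
        num += act.m * np.asarray(act.rule.centers)
        den += act.m
    return num / den


def decide(scores: np.ndarray, previous: str | None = None) -> str:
    """Pick the output state with the strictly largest score.

    On an exact tie the previous decision wins if it is among the tied
    states; otherwise the tied state earliest in the fixed output order.
    """
    scores = np.asarray(scores, dtype=float)
    best = scores.max()
    tied = [MOTION_STATES[i] for i in np.flatnonzero(scores == best)]
    if previous is not None and previous in tied:
        return previous
    return tied[0]


def infer_step(
    w1: np.ndarray,
    w2: np.ndarray,
    table: RuleTable,
    previous: str | None = None,
) -> tuple[np.ndarray, str]:
    """One full inference step: activate, defuzzify, decide."""
    scores = defuzzify(activate(w1, w2, table))
    return scores, decide(scores, previous)
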
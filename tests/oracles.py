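"""Independent reference implementations used only to cross-check the engine.

These deliberately mirror the published pseudocode and definitions as
literally as possible (full 36-term sums, naive loops) and share no code
with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np

from fuzzymotion.rulebase import CENTER_VALUES, RuleTable
from fuzzymotion.vocab import FUZZY_LABELS, MOTION_STATES


def literal_defuzz_scores(w1, w2, table: RuleTable) -> np.ndarray:
    """Literal rule-evaluation + defuzzification: sum all 36 MIN terms.

    For each output state, numerator = sum over every one of the 36 rules of
    MIN(weight of label_1 on module 1, weight of label_2 on module 2) times
    the rule's center value for that state; denominator = the same sum of
    MIN terms without the center values.  Rules with a zero MIN contribute
    zero to both, so no activation filtering is needed.
    """
    num = np.zeros(len(MOTION_STATES))
    den = 0.0
    for i, l1 in enumerate(FUZZY_LABELS):
        for j, l2 in enumerate(FUZZY_LABELS):
            m = min(w1[i], w2[j])
            rule = table.rule_for(l1, l2)
            for s in range(len(MOTION_STATES)):
                num[s] += m * CENTER_VALUES[rule.strengths[s]]
            den += m
    return num / den


def literal_defuzz_scores_batch(W1, W2, table: RuleTable) -> np.ndarray:
    """Vectorized literal 36-term transcription for (n, 6) weight batches.

    Identical arithmetic to :func:`literal_defuzz_scores` — all 36 MIN
    terms, weighted by the 36x5 center-value matrix — just evaluated for
    many weight pairs at once.
    """
    centers = np.array(
        [
            [CENTER_VALUES[s] for s in table.rule_for(l1, l2).strengths]
            for l1 in FUZZY_LABELS
            for l2 in FUZZY_LABELS
        ]
    )  # (36, 5) in rule order
    m = np.minimum(W1[:, :, None], W2[:, None, :]).reshape(len(W1), 36)
    return (m @ centers) / m.sum(axis=1, keepdims=True)


def argmax_with_tie_rule(scores, previous) -> str:
    """Brute-force linear scan: largest score, ties prefer previous else order."""
    best = max(scores)
    tied = [MOTION_STATES[i] for i, s in enumerate(scores) if s == best]
    return previous if previous in tied else tied[0]


def segment_means_by_label(recording, label, sign=None) -> float:
    """One-pass loop recomputation of a pooled segment mean (both channels)."""
    total, count = 0.0, 0
    for ch in (recording.channel_1, recording.channel_2):
        for value, lab in zip(ch, recording.labels):
            if lab != label:
                continue
            if sign == "neg" and value >= 0:
                continue
            if sign == "pos" and value <= 0:
                continue
            total += value
            count += 1
    return total / count


def naive_window_means(values, k):
    """Per-block loop mean, independent of the reshape-based implementation."""
    out = []
    for start in range(0, len(values) - k + 1, k):
        block = values[start : start + k]
        out.append(sum(block) / k)
    return out


def tally_accuracy(pairs) -> float:
    """Brute-force percentage of (predicted, truth) pairs that agree."""
    ok = sum(1 for p, t in pairs if p == t)
    return 100.0 * ok / len(pairs)
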
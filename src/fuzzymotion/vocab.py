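"""Shared vocabularies: fuzzy label names, motion states, decision codes."""

from __future__ import annotations

# Six linguistic labels of the input membership function, in the fixed order
# they appear along the voltage axis (most negative to most positive).
FUZZY_LABELS: tuple[str, ...] = ("High_N", "Low_N", "Off", "Low", "Med", "High")
LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(FUZZY_LABELS)}

WRIST_EXTENSION = "wrist_extension"
ULNAR_DEVIATION = "ulnar_deviation"
FINGER_FLEXION = "finger_flexion"
WRIST_FLEXION = "wrist_flexion"
OFF_STATE = "off_state"
REST = "rest"

# Classifier output states in the fixed rule-table column order.
MOTION_STATES: tuple[str, ...] = (
    WRIST_EXTENSION,
    ULNAR_DEVIATION,
    FINGER_FLEXION,
    WRIST_FLEXION,
    OFF_STATE,
)
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(MOTION_STATES)}

# Ground-truth labels a recording may carry, per sample.
SEGMENT_LABELS: tuple[str, ...] = (
    REST,
    WRIST_EXTENSION,
    ULNAR_DEVIATION,
    FINGER_FLEXION,
    WRIST_FLEXION,
)

# The four active motions in the order used to enumerate sequence permutations.
ACTIVE_MOTIONS: tuple[str, ...] = (
    WRIST_EXTENSION,
    ULNAR_DEVIATION,
    FINGER_FLEXION,
    WRIST_FLEXION,
)

# Integer codes used in decision streams on disk (and on plot axes):
# 1 = off state, 2 = wrist extension, 3 = ulnar deviation,
# 4 = finger flexion, 5 = wrist flexion.
DECISION_CODES: dict[str, int] = {
    OFF_STATE: 1,
    WRIST_EXTENSION: 2,
    ULNAR_DEVIATION: 3,
    FINGER_FLEXION: 4,
    WRIST_FLEXION: 5,
}
CODE_TO_STATE: dict[int, str] = {v: k for k, v in DECISION_CODES.items()}


def truth_to_state(label: str) -> str:
    """Map a ground-truth segment label onto the classifier's output vocabulary.

    A resting segment corresponds to the ``off_state`` decision; the four
    active motions map to themselves.
    """
    return OFF_STATE if label == REST else label
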
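"""The 36-entry fuzzy rule base mapping label pairs to motion strengths.

Each rule reads "if module 1 is <label_1> and module 2 is <label_2> then the
strength of each output state is <Low|Med|High>", with one strength per
output state in the fixed column order (wrist extension, ulnar deviation,
finger flexion, wrist flexion, off state).  Strength levels carry the center
values used by defuzzification: Low = 0.5, Med = 1, High = 2.

The shipped default table reproduces the 18 published rows verbatim; the 18
rows elided in the published table cannot be recovered and are filled by a
documented completion scheme (all-Low, plus the mirror of a published rule
when only one direction of a label pair is published).  Every filled row is
flagged ``inferred`` so the completion is never silently presented as
measured behaviour, and the whole table is an ordinary config artifact that
can be replaced from file — in deployment the rules are tuned per wearer and
session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RuleTableError
from .vocab import FUZZY_LABELS, LABEL_INDEX, MOTION_STATES

STRENGTH_LEVELS = ("Low", "Med", "High")

#: Center value w of each output strength level, used in the defuzzification
#: weighted average: High = 2, Med = 1, Low = 0.5.
CENTER_VALUES: dict[str, float] = {"Low": 0.5, "Med": 1.0, "High": 2.0}


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: an ordered label pair and five output strengths."""

    label_1: str
    label_2: str
    strengths: tuple[str, str, str, str, str]
    inferred: bool = False

    def __post_init__(self) -> None:
        for lab in (self.label_1, self.label_2):
            if lab not in FUZZY_LABELS:
                raise RuleTableError(f"unknown fuzzy label {lab!r}")
        if len(self.strengths) != len(MOTION_STATES):
            raise RuleTableError(
                f"rule ({self.label_1}, {self.label_2}) must give "
                f"{len(MOTION_STATES)} strengths, got {len(self.strengths)}"
            )
        for s in self.strengths:
            if s not in STRENGTH_LEVELS:
                raise RuleTableError(
                    f"illegal strength token {s!r} in rule "
                    f"({self.label_1}, {self.label_2}); expected one of {STRENGTH_LEVELS}"
                )

    @property
    def index(self) -> int:
        """1-based rule number in the canonical 6x6 enumeration."""
        return 6 * LABEL_INDEX[self.label_1] + LABEL_INDEX[self.label_2] + 1

    @property
    def centers(self) -> tuple[float, ...]:
        """Center values of this rule's five strengths."""
        return tuple(CENTER_VALUES[s] for s in self.strengths)


@dataclass
class RuleTable:
    """A complete rule base: exactly one rule per ordered label pair."""

    rules: dict[tuple[str, str], Rule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(a, b) for a in FUZZY_LABELS for b in FUZZY_LABELS}
        got = set(self.rules)
        missing = sorted(expected - got)
        if missing:
            raise RuleTableError(f"rule table incomplete; missing label pairs: {missing}")
        extra = sorted(got - expected)
        if extra:
            raise RuleTableError(f"rule table has unknown label pairs: {extra}")

    def __len__(self) -> int:
        return len(self.rules)

    def rule_for(self, label_1: str, label_2: str) -> Rule:
        return self.rules[(label_1, label_2)]

    def ordered(self) -> list[Rule]:
        """Rules sorted by their canonical 1-based index."""
        return sorted(self.rules.values(), key=lambda r: r.index)

    def center_matrix(self) -> np.ndarray:
        """Shape (6, 6, 5) array of center values indexed by label pair."""
        mat = np.empty((6, 6, len(MOTION_STATES)))
        for (l1, l2), rule in self.rules.items():
            mat[LABEL_INDEX[l1], LABEL_INDEX[l2]] = rule.centers
        return mat

    # ------------------------------------------------------------------ I/O

    def to_records(self) -> list[dict]:
        return [
            {
                "label_1": r.label_1,
                "label_2": r.label_2,
                **{state: r.strengths[i] for i, state in enumerate(MOTION_STATES)},
                "inferred": r.inferred,
            }
            for r in self.ordered()
        ]

    def save(self, path: str | Path) -> None:
        """Write the table as JSON (``.json``) or CSV (anything else)."""
        path = Path(path)
        records = self.to_records()
        if path.suffix.lower() == ".json":
            with open(path, "w") as fh:
                json.dump(records, fh, indent=1)
        else:
            pd.DataFrame.from_records(records).to_csv(path, index=False)


# The 18 published rows, keyed by (module-1 label, module-2 label), strengths
# in output-state column order (WE, UD, FF, WF, off).
_PUBLISHED_ROWS: dict[tuple[str, str], tuple[str, str, str, str, str]] = {
    ("High_N", "High_N"): ("High", "Low", "Low", "Low", "Low"),   # rule 1
    ("High_N", "Low_N"): ("Med", "Low", "Low", "Low", "Low"),     # rule 2
    ("High_N", "Off"): ("Low", "Low", "Low", "Low", "Low"),       # rule 3
    ("Low_N", "High_N"): ("Med", "Low", "Low", "Low", "Low"),     # rule 7
    ("Low_N", "Low_N"): ("Med", "Low", "Low", "Low", "Med"),      # rule 8
    ("Low_N", "Off"): ("Low", "Low", "Low", "Low", "Med"),        # rule 9
    ("Off", "High_N"): ("Low", "Low", "Low", "Low", "Low"),       # rule 13
    ("Off", "Low_N"): ("Low", "Low", "Low", "Low", "Med"),        # rule 14
    ("Off", "Off"): ("Low", "Low", "Low", "Low", "High"),         # rule 15
    ("Low", "Off"): ("Low", "High", "Low", "Low", "Med"),         # rule 21
    ("Low", "Low"): ("Low", "Med", "Low", "Low", "Med"),          # rule 22
    ("Low", "Med"): ("Low", "Low", "Low", "Low", "Low"),          # rule 23
    ("Med", "Low"): ("Low", "Med", "Low", "Low", "Low"),          # rule 28
    ("Med", "Med"): ("Low", "Low", "Med", "Low", "Low"),          # rule 29
    ("Med", "High"): ("Low", "Low", "High", "Low", "Low"),        # rule 30
    ("High", "Low"): ("Low", "Low", "Low", "Low", "Low"),         # rule 34
    ("High", "Med"): ("Low", "Low", "Med", "Med", "Low"),         # rule 35
    ("High", "High"): ("Low", "Low", "Low", "High", "Low"),       # rule 36
}

_ALL_LOW = ("Low", "Low", "Low", "Low", "Low")


def published_rows() -> dict[tuple[str, str], tuple[str, str, str, str, str]]:
    """The 18 published rule rows (a copy; keys are label pairs)."""
    return dict(_PUBLISHED_ROWS)


def default_rule_table() -> RuleTable:
    """Build the default table: 18 published rows + documented completion.

    Completion of the 18 elided rows: if the transposed pair is published,
    mirror its strengths (symmetry between modules, as exhibited by the
    published transposed pairs that agree); otherwise all outputs are Low.
    Completed rows carry ``inferred=True``.
    """
    rules: dict[tuple[str, str], Rule] = {}
    for pair, strengths in _PUBLISHED_ROWS.items():
        rules[pair] = Rule(pair[0], pair[1], strengths, inferred=False)
    for l1 in FUZZY_LABELS:
        for l2 in FUZZY_LABELS:
            if (l1, l2) in rules:
                continue
            mirror = _PUBLISHED_ROWS.get((l2, l1))
            strengths = mirror if mirror is not None else _ALL_LOW
            rules[(l1, l2)] = Rule(l1, l2, strengths, inferred=True)
    return RuleTable(rules)


def load_rule_table(path: str | Path) -> RuleTable:
    """Load and validate a rule table from a JSON or CSV file.

    Raises :class:`RuleTableError` naming any missing or duplicate label
    pair and any unknown label or strength token.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            with open(path) as fh:
                records = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RuleTableError(f"{path}: not valid JSON: {exc}") from exc
        if not isinstance(records, list):
            raise RuleTableError(f"{path}: rule table JSON must be a list of objects")
    else:
        try:
            records = pd.read_csv(path).to_dict(orient="records")
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise RuleTableError(f"{path}: could not parse CSV: {exc}") from exc

    rules: dict[tuple[str, str], Rule] = {}
    for rec in records:
        try:
            l1, l2 = rec["label_1"], rec["label_2"]
            strengths = tuple(rec[state] for state in MOTION_STATES)
        except KeyError as exc:
            raise RuleTableError(f"{path}: rule entry missing field {exc}") from exc
        if (l1, l2) in rules:
            raise RuleTableError(f"{path}: duplicate rule for label pair ({l1}, {l2})")
        rules[(l1, l2)] = Rule(l1, l2, strengths, inferred=bool(rec.get("inferred", False)))
    return RuleTable(rules)


def default_rule_table_path() -> Path:
    """Path of the rule-table JSON shipped with the package."""
    return Path(__file__).parent / "data" / "default_rules.json"
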
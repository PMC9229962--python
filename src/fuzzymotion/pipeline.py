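"""End-to-end classification pipeline and accuracy evaluation.

The raw 1 kHz recording is reduced to non-overlapping 5-sample window means
per channel; each window is fuzzified on both channels, run through the rule
base, defuzzified, and decided, yielding one decision (plus the five
defuzzification scores) per window.  Predictions are scored against windowed
ground truth with two per-motion accuracy rates: rate 1 pools every
sequence, rate 2 pools only sequences not excluded as detection failures.

Windows whose centers fall within a configurable transition margin (default
250 ms) of a ground-truth label change are omitted from both rates: motion
changes are physically gradual, so scoring inside the ramp is ill-posed.  A
detection failure is operationalized as at least one second of contiguous
misclassification inside a single motion plateau.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FuzzymotionError, StreamError
from .inference import infer_step
from .membership import CalibrationConstants, build_grid, fuzzify_many
from .recording import LabeledRecording
from .rulebase import RuleTable
from .vocab import (
    CODE_TO_STATE,
    DECISION_CODES,
    MOTION_STATES,
    OFF_STATE,
    truth_to_state,
)

#: Minimum duration of contiguous in-plateau misclassification that counts
#: as a detection failure (seconds).
FAILURE_MIN_S = 1.0

DECISION_COLUMNS = (
    "window_index",
    "time_s",
    "score_WE",
    "score_UD",
    "score_FF",
    "score_WF",
    "score_off",
    "decision",
)


@dataclass
class WindowedRecording:
    """Per-window channel means and majority ground-truth labels."""

    time_s: np.ndarray  # window-center times
    channel_1: np.ndarray
    channel_2: np.ndarray
    labels: np.ndarray | None
    window_s: float


@dataclass
class DecisionStream:
    """One decision and five defuzzification scores per window."""

    time_s: np.ndarray
    scores: np.ndarray  # shape (n_windows, 5), MOTION_STATES order
    decision: np.ndarray  # output-state name per window
    truth: np.ndarray | None  # windowed ground-truth segment label, if known
    window_s: float

    def __len__(self) -> int:
        return len(self.decision)

    @property
    def decision_codes(self) -> np.ndarray:
        """Integer decision codes (1 = off ... 5 = wrist flexion)."""
        return np.asarray([DECISION_CODES[d] for d in self.decision])


@dataclass(frozen=True)
class FailureEvent:
    """A sustained misclassification inside one ground-truth plateau."""

    sequence_id: str
    true_state: str
    start_s: float
    end_s: float


@dataclass
class EvalReport:
    """Per-motion accuracy rates and flagged detection failures."""

    accuracy_rate_1: dict[str, float | None]
    accuracy_rate_2: dict[str, float | None]
    overall_accuracy: float
    failure_sequences: list[str]
    failure_events: list[FailureEvent]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy_rate_1": self.accuracy_rate_1,
            "accuracy_rate_2": self.accuracy_rate_2,
            "overall_accuracy": self.overall_accuracy,
            "failure_sequences": list(self.failure_sequences),
            "failure_events": [
                {
                    "sequence_id": ev.sequence_id,
                    "true_state": ev.true_state,
                    "start_s": ev.start_s,
                    "end_s": ev.end_s,
                }
                for ev in self.failure_events
            ],
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def window_means(recording: LabeledRecording, k: int = 5) -> WindowedRecording:
    """Reduce a recording to means over non-overlapping blocks of ``k`` samples.

    A trailing block shorter than ``k`` is dropped.  Each window carries the
    majority ground-truth label of its samples, ties going to the label that
    occurs earlier within the window.
    """
    if k < 1:
        raise FuzzymotionError(f"window length must be >= 1 sample, got {k}")
    n_windows = recording.n_samples // k
    if n_windows == 0:
        raise FuzzymotionError(
            f"recording of {recording.n_samples} samples is shorter than one window of {k}"
        )
    n_used = n_windows * k
    ch1 = recording.channel_1[:n_used].reshape(n_windows, k).mean(axis=1)
    ch2 = recording.channel_2[:n_used].reshape(n_windows, k).mean(axis=1)
    window_s = k / recording.sample_rate
    time_s = (np.arange(n_windows) + 0.5) * window_s

    labels = None
    if recording.labels is not None:
        blocks = recording.labels[:n_used].reshape(n_windows, k)
        labels = np.empty(n_windows, dtype=object)
        uniform = np.all(blocks == blocks[:, :1], axis=1)
        labels[uniform] = blocks[uniform, 0]
        for i in np.flatnonzero(~uniform):
            labels[i] = _majority_label(blocks[i])
    return WindowedRecording(time_s, ch1, ch2, labels, window_s)


def _majority_label(block: np.ndarray) -> str:
    counts: dict[str, int] = {}
    for lab in block:  # first-occurrence order breaks ties toward the earlier label
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    for lab, c in counts.items():
        if c == best:
            return lab
    raise AssertionError("unreachable")


def classify_stream(
    recording: LabeledRecording,
    calib: CalibrationConstants,
    table: RuleTable,
    window_samples: int = 5,
) -> DecisionStream:
    """Run the full fuzzify / activate / defuzzify / decide chain per window.

    The previous decision threads through for tie-breaking, initialized to
    the off state (the protocol starts at rest).
    """
    grid = build_grid(calib)
    windowed = window_means(recording, window_samples)
    w1 = fuzzify_many(windowed.channel_1, grid)
    w2 = fuzzify_many(windowed.channel_2, grid)

    n = len(windowed.time_s)
    scores = np.empty((n, len(MOTION_STATES)))
    decisions = np.empty(n, dtype=object)
    previous = OFF_STATE
    for i in range(n):
        scores[i], previous = infer_step(w1[i], w2[i], table, previous)
        decisions[i] = previous
    return DecisionStream(windowed.time_s, scores, decisions, windowed.labels, windowed.window_s)


def _included_mask(truth_states: np.ndarray, time_s: np.ndarray, window_s: float, margin_s: float) -> np.ndarray:
    """Windows not within ``margin_s`` of a ground-truth label change."""
    mask = np.ones(len(truth_states), dtype=bool)
    if margin_s <= 0:
        return mask
    change = np.flatnonzero(truth_states[1:] != truth_states[:-1]) + 1
    for idx in change:
        boundary = time_s[idx] - window_s / 2.0  # true change time: start of first new-label window
        mask &= np.abs(time_s - boundary) > margin_s
    return mask


def _plateau_runs(truth_states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start, stop) of constant ground-truth state."""
    runs = []
    start = 0
    for i in range(1, len(truth_states) + 1):
        if i == len(truth_states) or truth_states[i] != truth_states[start]:
            runs.append((start, i))
            start = i
    return runs


def accuracy_rates(
    streams: Mapping[str, DecisionStream],
    transition_margin_s: float = 0.25,
    excluded_sequences: list[str] | None = None,
) -> EvalReport:
    """Score decision streams against their ground truth.

    Parameters
    ----------
    streams:
        Mapping from sequence identifier to a :class:`DecisionStream` whose
        ``truth`` labels are set.
    transition_margin_s:
        Windows whose centers lie within this margin of a ground-truth label
        change are omitted from both rates (0 disables).
    excluded_sequences:
        Sequences excluded from accuracy rate 2.  ``None`` (default) excludes
        exactly the automatically flagged failure sequences, mirroring the
        with/without-failure-cases reading of the two rates.
    """
    if transition_margin_s < 0:
        raise FuzzymotionError("transition_margin_s must be >= 0")

    per_seq: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    failure_events: list[FailureEvent] = []
    for seq_id, stream in streams.items():
        if stream.truth is None:
            raise StreamError(f"sequence {seq_id!r} has no ground-truth labels")
        if len(stream.truth) != len(stream.decision):
            raise StreamError(
                f"sequence {seq_id!r}: {len(stream.decision)} predictions vs "
                f"{len(stream.truth)} truth windows"
            )
        truth_states = np.asarray([truth_to_state(t) for t in stream.truth], dtype=object)
        included = _included_mask(truth_states, stream.time_s, stream.window_s, transition_margin_s)
        correct = stream.decision == truth_states
        per_seq[seq_id] = (truth_states, included, correct)
        failure_events.extend(
            _find_failures(seq_id, truth_states, included, correct, stream.time_s, stream.window_s)
        )

    failure_sequences = sorted({ev.sequence_id for ev in failure_events})
    if excluded_sequences is None:
        excluded = set(failure_sequences)
    else:
        excluded = set(excluded_sequences)

    def _pool(seq_ids) -> dict[str, float | None]:
        rates: dict[str, float | None] = {}
        for state in MOTION_STATES:
            n_tot = n_ok = 0
            for sid in seq_ids:
                truth_states, included, correct = per_seq[sid]
                sel = included & (truth_states == state)
                n_tot += int(sel.sum())
                n_ok += int((sel & correct).sum())
            rates[state] = 100.0 * n_ok / n_tot if n_tot else None
        return rates

    all_ids = list(per_seq)
    rate1 = _pool(all_ids)
    rate2 = _pool([s for s in all_ids if s not in excluded])

    n_tot = sum(int(inc.sum()) for _, inc, _ in per_seq.values())
    n_ok = sum(int((inc & cor).sum()) for _, inc, cor in per_seq.values())
    overall = 100.0 * n_ok / n_tot if n_tot else float("nan")

    return EvalReport(
        accuracy_rate_1=rate1,
        accuracy_rate_2=rate2,
        overall_accuracy=overall,
        failure_sequences=failure_sequences,
        failure_events=failure_events,
        config={
            "transition_margin_s": transition_margin_s,
            "excluded_sequences": sorted(excluded),
            "failure_min_s": FAILURE_MIN_S,
        },
    )


def _find_failures(
    seq_id: str,
    truth_states: np.ndarray,
    included: np.ndarray,
    correct: np.ndarray,
    time_s: np.ndarray,
    window_s: float,
) -> list[FailureEvent]:
    """Contiguous misclassified runs >= FAILURE_MIN_S within one plateau."""
    events = []
    for start, stop in _plateau_runs(truth_states):
        idx = np.arange(start, stop)[included[start:stop]]
        run: list[int] = []
        for i in list(idx) + [-1]:  # sentinel flushes the last run
            if i >= 0 and not correct[i] and (not run or i == run[-1] + 1):
                run.append(i)
                continue
            if run and len(run) * window_s >= FAILURE_MIN_S:
                events.append(
                    FailureEvent(
                        sequence_id=seq_id,
                        true_state=str(truth_states[start]),
                        start_s=float(time_s[run[0]] - window_s / 2),
                        end_s=float(time_s[run[-1]] + window_s / 2),
                    )
                )
            run = [i] if (i >= 0 and not correct[i]) else []
    return events


# ------------------------------------------------------------------ disk I/O

def write_decisions_csv(stream: DecisionStream, path: str | Path) -> None:
    """Write a decision stream as CSV with integer decision codes 1-5."""
    df = pd.DataFrame(
        {
            "window_index": np.arange(len(stream)),
            "time_s": stream.time_s,
            "score_WE": stream.scores[:, 0],
            "score_UD": stream.scores[:, 1],
            "score_FF": stream.scores[:, 2],
            "score_WF": stream.scores[:, 3],
            "score_off": stream.scores[:, 4],
            "decision": stream.decision_codes,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_decisions_csv(path: str | Path) -> DecisionStream:
    """Read a decision stream written by :func:`write_decisions_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in DECISION_COLUMNS if c not in df.columns]
    if missing:
        raise StreamError(f"{path}: missing decision columns {missing}")
    time_s = df["time_s"].to_numpy(dtype=float)
    window_s = float(np.median(np.diff(time_s))) if len(time_s) > 1 else float(2 * time_s[0])
    scores = df[["score_WE", "score_UD", "score_FF", "score_WF", "score_off"]].to_numpy(dtype=float)
    try:
        decision = np.asarray([CODE_TO_STATE[int(c)] for c in df["decision"]], dtype=object)
    except KeyError as exc:
        raise StreamError(f"{path}: unknown decision code {exc}") from exc
    return DecisionStream(time_s, scores, decision, None, window_s)
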
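"""Two-channel labeled voltage recordings and their on-disk formats.

A recording is the raw material every other module consumes: two voltage
channels sampled at a nominal 1 kHz (one per sensor module worn over the
extensor / flexor carpi ulnaris), plus optional per-sample ground-truth
motion labels.

On disk a recording is a CSV with columns ``time_s, module_1_v, module_2_v``
and an optional ``label`` column; segment annotations are a JSON list of
``{"label": ..., "start_s": ..., "end_s": ...}`` half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FuzzymotionError
from .vocab import REST, SEGMENT_LABELS

SIGNAL_COLUMNS = ("time_s", "module_1_v", "module_2_v")


@dataclass(frozen=True)
class Segment:
    """A labeled half-open time interval ``[start_s, end_s)`` of a recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise FuzzymotionError(
                f"unknown segment label {self.label!r}; expected one of {SEGMENT_LABELS}"
            )
        if not self.end_s > self.start_s:
            raise FuzzymotionError(
                f"segment {self.label!r} has non-positive duration "
                f"[{self.start_s}, {self.end_s})"
            )


@dataclass
class LabeledRecording:
    """Two-channel voltage time series with optional per-sample motion labels.

    Parameters
    ----------
    sample_rate:
        Sampling frequency in Hz (nominal 1000).
    channel_1, channel_2:
        Voltages per sample for sensor modules 1 and 2.
    labels:
        Per-sample ground-truth label from :data:`~fuzzymotion.vocab.SEGMENT_LABELS`,
        or ``None`` for an unlabeled recording.
    """

    sample_rate: float
    channel_1: np.ndarray
    channel_2: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.channel_1 = np.asarray(self.channel_1, dtype=float)
        self.channel_2 = np.asarray(self.channel_2, dtype=float)
        if self.sample_rate <= 0:
            raise FuzzymotionError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.channel_1.ndim != 1 or self.channel_2.ndim != 1:
            raise FuzzymotionError("channels must be one-dimensional")
        if len(self.channel_1) != len(self.channel_2):
            raise FuzzymotionError(
                f"channel length mismatch: {len(self.channel_1)} vs {len(self.channel_2)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.channel_1):
                raise FuzzymotionError(
                    f"labels length {len(self.labels)} does not match "
                    f"{len(self.channel_1)} samples"
                )
            unknown = set(self.labels) - set(SEGMENT_LABELS)
            if unknown:
                raise FuzzymotionError(f"unknown motion labels {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.channel_1)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        """Sample timestamps in seconds from the start of the recording."""
        return np.arange(self.n_samples) / self.sample_rate

    def with_labels(self, segments: list[Segment]) -> "LabeledRecording":
        """Return a copy whose labels come from a segment annotation list.

        Samples outside every segment are labeled ``rest``.  Interval edges
        are converted to sample indices by rounding, so a boundary that falls
        exactly on a sample is assigned robustly even when the sample rate
        was inferred from written timestamps.
        """
        labels = np.full(self.n_samples, REST, dtype=object)
        for seg in segments:
            i0 = max(0, int(round(seg.start_s * self.sample_rate)))
            i1 = min(self.n_samples, int(round(seg.end_s * self.sample_rate)))
            labels[i0:i1] = seg.label
        return LabeledRecording(self.sample_rate, self.channel_1, self.channel_2, labels)


def read_signal_csv(path: str | Path) -> LabeledRecording:
    """Load a recording from the standard signal CSV format.

    The sample rate is inferred from the median timestamp increment.
    """
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FuzzymotionError(f"{path}: missing required columns {missing}")
    if len(df) < 2:
        raise FuzzymotionError(f"{path}: need at least 2 samples to infer sample rate")
    dt = float(np.median(np.diff(df["time_s"].to_numpy(dtype=float))))
    if dt <= 0:
        raise FuzzymotionError(f"{path}: non-increasing time_s column")
    fs = 1.0 / dt
    if abs(fs - round(fs)) < 1e-6 * fs:  # snap timestamp round-off (e.g. 1/0.001)
        fs = float(round(fs))
    labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
    return LabeledRecording(
        sample_rate=fs,
        channel_1=df["module_1_v"].to_numpy(dtype=float),
        channel_2=df["module_2_v"].to_numpy(dtype=float),
        labels=labels,
    )


def write_signal_csv(recording: LabeledRecording, path: str | Path) -> None:
    """Write a recording in the standard signal CSV format."""
    data = {
        "time_s": recording.time_s,
        "module_1_v": recording.channel_1,
        "module_2_v": recording.channel_2,
    }
    if recording.labels is not None:
        data["label"] = recording.labels
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def load_segments(path: str | Path) -> list[Segment]:
    """Load segment annotations from JSON (list of label/start_s/end_s)."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise FuzzymotionError(f"{path}: segment annotations must be a JSON list")
    return [Segment(entry["label"], float(entry["start_s"]), float(entry["end_s"])) for entry in raw]


def save_segments(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"label": s.label, "start_s": s.start_s, "end_s": s.end_s} for s in segments],
            fh,
            indent=2,
        )
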
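"""Synthetic two-channel bracelet recordings with ground-truth labels.

No measured recordings are distributed with the sensor study this package
models, so every other module is exercised on synthetic signals that emulate
the measured per-motion signatures: near-zero baseline at rest, negative
excursions on both channels during wrist extension, and channel-specific
positive excursions during the other three motions, each motion plateau held
about 5 s inside a 30 s protocol (rest, four consecutive motions, rest).

The generator is deliberately simple — per-motion plateau levels, linear
transition ramps, i.i.d. Gaussian noise, optional linear drift — and fully
reproducible from its seed.  The canonical signal model places each motion
exactly at the label pair of its dominant rule, so a noise-free recording is
classified perfectly inside plateaus; a dedicated stress option narrows the
wrist-extension-to-ulnar-deviation level gap to reproduce the sensor's
documented failure mode (the contact-area change between those two motions
is small).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FuzzymotionError
from .membership import CalibrationConstants, build_grid
from .recording import LabeledRecording, write_signal_csv
from .vocab import (
    ACTIVE_MOTIONS,
    FINGER_FLEXION,
    REST,
    SEGMENT_LABELS,
    ULNAR_DEVIATION,
    WRIST_EXTENSION,
    WRIST_FLEXION,
)


@dataclass(frozen=True)
class MotionScript:
    """An ordered list of (motion label, duration in seconds) segments."""

    segments: tuple[tuple[str, float], ...]
    sample_rate: float = 1000.0
    name: str = "script"

    def __post_init__(self) -> None:
        if not self.segments:
            raise FuzzymotionError("a motion script needs at least one segment")
        for label, duration in self.segments:
            if label not in SEGMENT_LABELS:
                raise FuzzymotionError(f"unknown motion label {label!r} in script")
            if duration <= 0:
                raise FuzzymotionError(f"segment {label!r} has non-positive duration {duration}")
        if self.sample_rate <= 0:
            raise FuzzymotionError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.segments)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sample_rate_hz": self.sample_rate,
            "segments": [{"motion": m, "duration_s": d} for m, d in self.segments],
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "MotionScript":
        with open(path) as fh:
            raw = json.load(fh)
        try:
            segments = tuple((s["motion"], float(s["duration_s"])) for s in raw["segments"])
        except KeyError as exc:
            raise FuzzymotionError(f"{path}: motion script missing field {exc}") from exc
        return cls(
            segments=segments,
            sample_rate=float(raw.get("sample_rate_hz", 1000.0)),
            name=str(raw.get("name", Path(path).stem)),
        )


@dataclass(frozen=True)
class SignalModel:
    """Plateau levels plus noise/ramp/drift parameters of the generator.

    ``levels`` maps each motion label (including rest) to its (module 1,
    module 2) plateau voltages.  ``we_ud_stress`` in [0, 1) pulls the
    module-1 plateau of an ulnar-deviation segment that directly follows
    wrist extension toward the rest level by that fraction (0 disables).
    """

    levels: dict[str, tuple[float, float]]
    ramp_s: float = 0.2
    noise_sd: float = 0.0
    drift_per_s: float = 0.0
    we_ud_stress: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [m for m in SEGMENT_LABELS if m not in self.levels]
        if missing:
            raise FuzzymotionError(f"signal model missing plateau levels for {missing}")
        if self.noise_sd < 0 or self.ramp_s < 0:
            raise FuzzymotionError("noise_sd and ramp_s must be >= 0")
        if not 0.0 <= self.we_ud_stress < 1.0:
            raise FuzzymotionError(f"we_ud_stress must be in [0, 1), got {self.we_ud_stress}")

    def to_dict(self) -> dict:
        return {
            "levels": {m: list(lv) for m, lv in self.levels.items()},
            "ramp_s": self.ramp_s,
            "noise_sd": self.noise_sd,
            "drift_per_s": self.drift_per_s,
            "we_ud_stress": self.we_ud_stress,
            "seed": self.seed,
        }


def default_calibration() -> CalibrationConstants:
    """Anchors (-1, 0, +1) V: the demo calibration used when none is supplied."""
    return CalibrationConstants(-1.0, 0.0, 1.0)


def canonical_signal_model(
    calib: CalibrationConstants,
    *,
    noise_sd: float | None = None,
    ramp_s: float = 0.2,
    drift_per_s: float = 0.0,
    we_ud_stress: float = 0.0,
    seed: int = 0,
) -> SignalModel:
    """Plateau levels that place each motion at its dominant rule's label pair.

    rest at (x_o, x_o) [Off/Off]; wrist extension just below the lower
    saturation boundary on both channels [High_N/High_N]; ulnar deviation at
    (Low peak, x_o) [Low/Off]; finger flexion at (x_p, just above the upper
    boundary) [Med/High]; wrist flexion just above the upper boundary on
    both channels [High/High].  "Just beyond" is 5% of (x_p - x_o).

    ``noise_sd=None`` uses the default 0.1 * (x_p - x_o), a noise floor that
    exercises the 50%-overlap regions of the membership function without
    routinely crossing a full label.
    """
    grid = build_grid(calib)
    delta = 0.05 * (calib.x_p - calib.x_o)
    if noise_sd is None:
        noise_sd = 0.1 * (calib.x_p - calib.x_o)
    levels = {
        REST: (calib.x_o, calib.x_o),
        WRIST_EXTENSION: (grid.outer_neg - delta, grid.outer_neg - delta),
        ULNAR_DEVIATION: ((calib.x_o + calib.x_p) / 2.0, calib.x_o),
        FINGER_FLEXION: (calib.x_p, grid.outer_pos + delta),
        WRIST_FLEXION: (grid.outer_pos + delta, grid.outer_pos + delta),
    }
    return SignalModel(
        levels=levels,
        ramp_s=ramp_s,
        noise_sd=float(noise_sd),
        drift_per_s=drift_per_s,
        we_ud_stress=we_ud_stress,
        seed=seed,
    )


def calibration_signal_model(
    calib: CalibrationConstants,
    *,
    noise_sd: float | None = None,
    seed: int = 0,
) -> SignalModel:
    """Plateau levels at the membership anchors themselves, without ramps.

    Used to produce calibration recordings: wrist extension sits at
    (x_n, x_n), rest at (x_o, x_o) and all three positive motions at
    (x_p, x_p), so segment means recover the anchors directly.  Ramps are
    disabled because a calibration recording is a set of held plateaus and
    ramp samples would bias the segment means.
    """
    if noise_sd is None:
        noise_sd = 0.1 * (calib.x_p - calib.x_o)
    levels = {
        REST: (calib.x_o, calib.x_o),
        WRIST_EXTENSION: (calib.x_n, calib.x_n),
        ULNAR_DEVIATION: (calib.x_p, calib.x_p),
        FINGER_FLEXION: (calib.x_p, calib.x_p),
        WRIST_FLEXION: (calib.x_p, calib.x_p),
    }
    return SignalModel(levels=levels, ramp_s=0.0, noise_sd=float(noise_sd), seed=seed)


def simulate(script: MotionScript, model: SignalModel) -> LabeledRecording:
    """Render a motion script into a labeled two-channel recording.

    Each segment holds its plateau level; an incoming segment starts with a
    linear ramp of ``ramp_s`` (clipped to the segment length) from the
    previous level, and ramp samples carry the incoming segment's label.
    Gaussian noise and optional linear drift are added per sample.  The
    result is a pure function of (script, model) including the seed.
    """
    fs = script.sample_rate
    rng = np.random.default_rng(model.seed)

    ch_levels: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    prev_level: tuple[float, float] | None = None
    prev_motion: str | None = None
    for motion, duration in script.segments:
        n = int(round(duration * fs))
        level = model.levels[motion]
        if (
            model.we_ud_stress > 0
            and motion == ULNAR_DEVIATION
            and prev_motion == WRIST_EXTENSION
        ):
            rest1 = model.levels[REST][0]
            level = (rest1 + (1.0 - model.we_ud_stress) * (level[0] - rest1), level[1])
        seg = np.empty((n, 2))
        seg[:] = level
        if prev_level is not None and model.ramp_s > 0:
            n_ramp = min(int(round(model.ramp_s * fs)), n)
            for c in range(2):
                seg[:n_ramp, c] = np.linspace(prev_level[c], level[c], n_ramp + 1)[1:]
        ch_levels.append(seg)
        labels.append(np.full(n, motion, dtype=object))
        prev_level = level
        prev_motion = motion

    clean = np.concatenate(ch_levels)
    lab = np.concatenate(labels)
    n_total = clean.shape[0]
    signal = clean + rng.normal(0.0, model.noise_sd, size=(n_total, 2))
    if model.drift_per_s:
        signal += (model.drift_per_s * np.arange(n_total) / fs)[:, None]
    return LabeledRecording(fs, signal[:, 0], signal[:, 1], lab)


def make_sequence_script(
    motions: tuple[str, ...],
    *,
    rest_s: float = 5.0,
    motion_s: float = 5.0,
    sample_rate: float = 1000.0,
    name: str | None = None,
) -> MotionScript:
    """Wrap a motion ordering in the standard rest / motions / rest protocol."""
    segments = (
        (REST, rest_s),
        *((m, motion_s) for m in motions),
        (REST, rest_s),
    )
    if name is None:
        name = "-".join(m.split("_")[0] for m in motions)
    return MotionScript(segments=segments, sample_rate=sample_rate, name=name)


def all_motion_sequences(
    *,
    rest_s: float = 5.0,
    motion_s: float = 5.0,
    sample_rate: float = 1000.0,
) -> list[MotionScript]:
    """The 24 permutations of the four motions, each in the 30 s protocol.

    Ordered lexicographically with respect to the canonical motion order
    (wrist extension, ulnar deviation, finger flexion, wrist flexion) and
    named ``seq_01`` ... ``seq_24``.
    """
    scripts = []
    for i, perm in enumerate(itertools.permutations(ACTIVE_MOTIONS), start=1):
        scripts.append(
            make_sequence_script(
                perm,
                rest_s=rest_s,
                motion_s=motion_s,
                sample_rate=sample_rate,
                name=f"seq_{i:02d}",
            )
        )
    return scripts


def write_provenance(script: MotionScript, model: SignalModel, path: str | Path) -> None:
    """Side-car JSON recording exactly how a synthetic recording was made."""
    with open(path, "w") as fh:
        json.dump({"script": script.to_dict(), "model": model.to_dict()}, fh, indent=2)


def simulate_to_csv(
    script: MotionScript,
    model: SignalModel,
    csv_path: str | Path,
) -> LabeledRecording:
    """Simulate and write the signal CSV plus its provenance side-car."""
    recording = simulate(script, model)
    csv_path = Path(csv_path)
    write_signal_csv(recording, csv_path)
    write_provenance(script, model, csv_path.with_suffix(".provenance.json"))
    return recording


__all__ = [
    "MotionScript",
    "SignalModel",
    "default_calibration",
    "canonical_signal_model",
    "calibration_signal_model",
    "simulate",
    "simulate_to_csv",
    "make_sequence_script",
    "all_motion_sequences",
    "write_provenance",
]
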
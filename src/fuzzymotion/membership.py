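"""Calibrated triangular input membership function and fuzzification.

The classifier reads each sensor channel through a single input membership
function built from three calibration anchors measured on the wearer:

* ``x_n`` — mean of the negative voltages seen during wrist extension,
* ``x_o`` — mean voltage during rest,
* ``x_p`` — mean of the positive voltages seen during the other three motions.

Six triangular membership functions with 50% overlap are centered, in order,
at::

    (3*x_n - x_o)/2,  x_n,  x_o,  (x_o + x_p)/2,  x_p,  (x_o + 3*x_p)/2
      High_N         Low_N  Off     Low           Med      High

Between adjacent peaks the two bracketing labels receive complementary
piecewise-linear weights (a partition of unity); beyond the outermost peaks a
single label saturates at weight 1.  Each fuzzification step therefore turns
one voltage into six label weights of which at most two are nonzero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CalibrationError
from .recording import LabeledRecording
from .vocab import (
    FUZZY_LABELS,
    REST,
    WRIST_EXTENSION,
    ULNAR_DEVIATION,
    FINGER_FLEXION,
    WRIST_FLEXION,
)

POSITIVE_MOTIONS = (ULNAR_DEVIATION, FINGER_FLEXION, WRIST_FLEXION)


@dataclass(frozen=True)
class CalibrationConstants:
    """The three voltage anchors that position all six membership triangles.

    Only the strict ordering ``x_n < x_o < x_p`` is enforced; in practice
    ``x_n`` is negative, ``x_o`` near zero and ``x_p`` positive, but the
    geometry of the membership function needs only the ordering.
    """

    x_n: float
    x_o: float
    x_p: float

    def __post_init__(self) -> None:
        if not (self.x_n < self.x_o < self.x_p):
            raise CalibrationError(
                "calibration constants must satisfy x_n < x_o < x_p, got "
                f"x_n={self.x_n}, x_o={self.x_o}, x_p={self.x_p}"
            )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"x_n": self.x_n, "x_o": self.x_o, "x_p": self.x_p}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationConstants":
        with open(path) as fh:
            raw = json.load(fh)
        try:
            return cls(float(raw["x_n"]), float(raw["x_o"]), float(raw["x_p"]))
        except KeyError as exc:
            raise CalibrationError(f"{path}: missing calibration field {exc}") from exc


@dataclass(frozen=True)
class MembershipGrid:
    """Peak positions of the six triangles, most negative to most positive.

    ``peaks[i]`` is where label ``FUZZY_LABELS[i]`` attains weight 1.  Beyond
    ``outer_neg`` (= peaks[0]) only High_N fires; beyond ``outer_pos``
    (= peaks[5]) only High fires.
    """

    peaks: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.peaks) != 6 or not all(
            a < b for a, b in zip(self.peaks, self.peaks[1:])
        ):
            raise CalibrationError(f"membership peaks must be 6 strictly increasing values, got {self.peaks}")

    @property
    def outer_neg(self) -> float:
        """Lower saturation boundary b1 = (3*x_n - x_o)/2."""
        return self.peaks[0]

    @property
    def outer_pos(self) -> float:
        """Upper saturation boundary b2 = (x_o + 3*x_p)/2."""
        return self.peaks[5]


def build_grid(calib: CalibrationConstants) -> MembershipGrid:
    """Place the six triangle peaks from the three calibration anchors."""
    x_n, x_o, x_p = calib.x_n, calib.x_o, calib.x_p
    return MembershipGrid(
        peaks=(
            (3.0 * x_n - x_o) / 2.0,
            x_n,
            x_o,
            (x_o + x_p) / 2.0,
            x_p,
            (x_o + 3.0 * x_p) / 2.0,
        )
    )


def fuzzify(v: float, grid: MembershipGrid) -> np.ndarray:
    """Convert one voltage into six label weights (order of ``FUZZY_LABELS``).

    Branch boundaries are upper-inclusive: a value exactly at a peak belongs
    to the branch below it, which assigns that peak's label weight 1.  Values
    above ``outer_pos`` saturate High = 1; values at or below ``outer_neg``
    saturate High_N = 1.
    """
    if not np.isfinite(v):
        raise CalibrationError(f"cannot fuzzify non-finite value {v!r}")
    return fuzzify_many(np.asarray([v], dtype=float), grid)[0]


def fuzzify_many(values: np.ndarray, grid: MembershipGrid) -> np.ndarray:
    """Vectorized :func:`fuzzify`: maps shape ``(n,)`` onto weights ``(n, 6)``."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise CalibrationError("cannot fuzzify non-finite values")
    peaks = np.asarray(grid.peaks)
    n = v.shape[0]
    weights = np.zeros((n, 6))

    high = v > peaks[5]
    low = v <= peaks[0]
    weights[high, 5] = 1.0
    weights[low, 0] = 1.0

    interior = ~(high | low)
    if np.any(interior):
        vi = v[interior]
        # segment index i such that peaks[i] < vi <= peaks[i+1]
        seg = np.searchsorted(peaks, vi, side="left") - 1
        span = peaks[seg + 1] - peaks[seg]
        w_lower = (peaks[seg + 1] - vi) / span
        rows = np.flatnonzero(interior)
        weights[rows, seg] = w_lower
        weights[rows, seg + 1] = 1.0 - w_lower
    return weights


def calibrate(recording: LabeledRecording) -> CalibrationConstants:
    """Estimate the three anchors from a labeled calibration recording.

    Pooled across both channels: ``x_n`` is the mean of negative-valued
    samples inside wrist-extension segments, ``x_o`` the mean of all samples
    inside rest segments, and ``x_p`` the mean of positive-valued samples
    inside ulnar-deviation / finger-flexion / wrist-flexion segments.
    """
    if recording.labels is None:
        raise CalibrationError("calibration requires a labeled recording")
    labels = recording.labels
    pooled = np.concatenate([recording.channel_1, recording.channel_2])
    pooled_labels = np.concatenate([labels, labels])

    rest_vals = pooled[pooled_labels == REST]
    we_vals = pooled[pooled_labels == WRIST_EXTENSION]
    we_neg = we_vals[we_vals < 0]
    pos_mask = np.isin(pooled_labels, POSITIVE_MOTIONS)
    pos_vals = pooled[pos_mask]
    pos_pos = pos_vals[pos_vals > 0]

    if rest_vals.size == 0:
        raise CalibrationError("calibration recording has no rest-labeled samples")
    if we_neg.size == 0:
        raise CalibrationError(
            "calibration recording has no negative-valued samples during wrist extension"
        )
    if pos_pos.size == 0:
        raise CalibrationError(
            "calibration recording has no positive-valued samples during "
            "ulnar deviation / finger flexion / wrist flexion"
        )

    x_n = float(we_neg.mean())
    x_o = float(rest_vals.mean())
    x_p = float(pos_pos.mean())
    if not (x_n < x_o < x_p):
        order = (
            f"x_n={x_n:.6g} (wrist-extension negatives), x_o={x_o:.6g} (rest), "
            f"x_p={x_p:.6g} (positive motions)"
        )
        raise CalibrationError(
            f"calibration yielded anchors violating x_n < x_o < x_p: {order}"
        )
    return CalibrationConstants(x_n, x_o, x_p)


def weights_as_dict(weights: np.ndarray) -> dict[str, float]:
    """Label-name view of a six-element weight vector (handy for display)."""
    return {name: float(w) for name, w in zip(FUZZY_LABELS, weights)}
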
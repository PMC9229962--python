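# Methods

## Model

`fuzzymotion` implements a Mamdani-style fuzzy inference classifier for a
two-channel forearm voltage signal. The processing chain per 5-sample
window is:

1. **Windowing.** Non-overlapping blocks of `window_samples` (default 5)
   raw samples are reduced to their mean per channel; a trailing partial
   block is dropped. At 1 kHz this yields one decision every 5 ms. Each
   window inherits the majority ground-truth label of its samples, ties
   going to the label that occurs earlier in the window.
2. **Fuzzification.** Each channel mean is mapped through one shared input
   membership function: six triangles with 50% overlap, peaks at
   `(3x_n - x_o)/2, x_n, x_o, (x_o + x_p)/2, x_p, (x_o + 3x_p)/2` for
   labels `High_N, Low_N, Off, Low, Med, High`. On the interval between
   adjacent peaks the lower label's weight is
   `(p_{i+1} - v)/(p_{i+1} - p_i)` and the upper label takes the
   complement — the only shape consistent with triangular memberships, 50%
   overlap and a partition of unity. Branch boundaries are
   upper-inclusive (a value exactly at a peak takes weight 1 on that
   label); values above the last peak saturate `High = 1`, values at or
   below the first peak saturate `High_N = 1`. Weights are exact
   constructions, so downstream "nonzero" tests compare against 0 exactly.
3. **Rule evaluation.** A rule exists for each of the 36 ordered label
   pairs; it fires iff both weights are nonzero, with firing strength
   `m = min(w1, w2)`. At most two labels are nonzero per channel, so 1–4
   rules fire per window.
4. **Defuzzification.** Per output state, `score = Σ m_i w_i / Σ m_i` over
   the fired rules, with center values Low = 0.5, Med = 1, High = 2. The
   denominator is shared across states, making each score a convex
   combination of center values in [0.5, 2].
5. **Decision.** Argmax over the five scores. An exact tie keeps the
   previous window's decision when it is among the tied states, otherwise
   the tied state earliest in the fixed order (WE, UD, FF, WF, off). The
   previous-decision state is initialized to the off state, matching a
   protocol that starts at rest. No further temporal smoothing or
   hysteresis is applied.

## Calibration

`calibrate()` estimates the anchors from a labeled recording, pooling both
channels: `x_n` = mean of negative samples in wrist-extension segments,
`x_o` = mean of rest segments, `x_p` = mean of positive samples in the
three positive-motion segments. A single shared calibration is used for
both channels by default (the membership thresholds are common to both
modules); per-channel overrides are possible by building separate grids.
Only the ordering `x_n < x_o < x_p` is enforced — not signs — because the
membership geometry needs only the ordering. Pooling `x_p` across the
three positive motions (rather than per motion) follows the anchor's
definition as "the" positive mean.

## Rule-table completion

Only 18 of the 36 rule rows are published. The shipped default fills the
other 18 with all-`Low` outputs, except that a pair whose transpose is
published takes the transposed row's strengths (the published transposed
pairs that exist agree with each other, which motivates the mirror).
Concretely the only non-trivial mirror is `(Off, Low)`, which takes the
`(Low, Off)` pattern (UD `High`, off `Med`). Every completed row carries
`inferred: true` in the table metadata so the completion is never
mistaken for measured behaviour, and the whole table is a replaceable
JSON/CSV artifact — on the real system the rules are re-tuned per wearer
and session. One published inconsistency is resolved in favour of the
center-value definition: the rule-evaluation pseudocode annotates a few
strengths with center values that contradict the Low/Med/High = 0.5/1/2
mapping; the mapping wins everywhere.

## Synthetic-signal generator

No measured recordings are available, so the generator emulates the
documented signal structure: per-motion plateau levels on both channels,
linear transition ramps, i.i.d. Gaussian noise, optional linear drift,
fully reproducible from a seed. The canonical model places each motion at
the label pair of its dominant rule — rest `(x_o, x_o)`, WE both channels
5% of `(x_p - x_o)` below the lower saturation boundary, UD
`((x_o+x_p)/2, x_o)`, FF `(x_p, b2 + 5%)`, WF both channels above `b2` —
so a noise-free recording is classified perfectly inside plateaus.
Defaults are the study conditions: 1 kHz sampling, 5 s plateaus, 24
sequence permutations in lexicographic order with 5 s rest bookends.

Parameter choices where no value was documented:

- **Noise floor** `0.1·(x_p - x_o)` (0.1 V on the demo calibration): the
  simplest model that routinely exercises the 50%-overlap regions of the
  membership function without crossing a full label at the plateau levels.
- **Ramp duration** 0.2 s: motions are performed at constant speed over a
  fraction of a second; ramp samples carry the incoming segment's label.
- **Demo calibration** anchors (−1, 0, +1) V, used by examples and the CLI
  when none is supplied.

The calibration model (`calibration_signal_model`) instead puts plateaus
at the anchors themselves — WE at `(x_n, x_n)`, positives at `(x_p, x_p)` —
with ramps disabled, because a calibration recording is a set of held
plateaus and labeled ramp samples would bias the segment means.

What the generator does **not** model: inter-channel noise correlation,
plateau-level variability from muscle fatigue/strength/speed, baseline
wander beyond linear drift, and the sensor's film/bridge/amplifier
physics. Passing tests therefore demonstrate the correctness of the
inference chain under its stated signal model, not field performance on
real wearers.

### Stress scenario

All documented detection failures on the real device occurred when the
motion changed from wrist extension to ulnar deviation, because the
contact-area change between those motions is small. The generator
reproduces this qualitatively: with `we_ud_stress = f`, the module-1
plateau of a UD segment that *directly follows* WE is pulled toward the
rest level by fraction `f` (default 0.9 in the CLI and examples). At
`f = 0.9` the degraded plateau fuzzifies to mostly `Off`, the off state
outscores UD for the whole plateau, and the evaluator flags exactly the
sequences containing a WE→UD transition — the failure mode as a
reproducible scenario, not a fitted number.

## Evaluation

Accuracy is per-window (the classifier's native output unit). Per motion,
rate 1 = 100 × correct/total windows with that true label pooled over all
sequences; rate 2 pools only non-excluded sequences. When no explicit
exclusion list is given, rate 2 excludes the automatically flagged failure
sequences — a failure being ≥ 1 s of contiguous misclassification within a
single ground-truth plateau, a reproducible stand-in for flagging failures
by visual inspection. Windows whose centers lie within
`transition_margin_s` (default 0.25 s, 0 disables) of a ground-truth label
change are excluded from both rates: movement transitions are physically
gradual, so those windows have no well-defined true label. Note rate 2 is
not guaranteed ≥ rate 1 in general; only the exclusion semantics are
defined.

## Numerical and degenerate-input choices

- Fuzzification rejects non-finite inputs; calibration rejects recordings
  missing any required segment kind and reports which anchor ordering a
  bad calibration violates.
- An empty activation list (impossible for valid weights) raises rather
  than defaulting to rest, so upstream bugs cannot hide.
- Decision ties are broken by temporal continuity (see above) to avoid
  label flicker on symmetric scores; the comparison is exact float
  equality, which arises in practice (e.g. plateaus at a triangle peak
  firing a single rule with two equal `Med` strengths).
- Sample rates inferred from written timestamps are snapped to the nearest
  integer when within 1 ppm, so CSV round-trips don't shift segment
  boundaries by a sample.

## Problem sizes

The test suite and the acceptance script run the full protocol: all 24
sequences × 30 s × 1 kHz (720 000 samples, 144 000 windows) per study
condition, 10⁴ random draws for the partition-of-unity check, and 10⁵
random weight pairs for the engine-versus-literal-transcription check
(tolerance 1e−12). Calibration recovery uses 5 s segments
(5 000 samples each) and asserts each anchor within `3·sd/√n` of a
segment.

## Known limitations

- The 18 inferred rule rows are a completion scheme, not recovered truth;
  behaviour on label pairs outside the published rows is only as good as
  that completion (all such pairs score every motion `Low`, so they
  effectively abstain).
- The default accuracy numbers are measured on synthetic signals; they
  characterize the algorithm under the generator's assumptions and are not
  comparable to accuracies measured on real recordings.
- No real-time/streaming interface; recordings are processed offline.
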